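"""Packaged worked-example data: published seven-cohort survey counts.

The packaged table carries the per-disease gene and sample counts reported
by a genome-wide survey of potentially damaging compound-heterozygous and
homozygous-alternate variants across seven pediatric trio cohorts (two
cancers, five structural birth defects), before and after control-cohort
background filtering, together with the unique-CH increments.  The
underlying per-variant data are controlled-access; these summary counts are
the public worked example against which the summary arithmetic of this
package can be exercised.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from .summary import DiseaseSummary

#: Median variants per sample before any processing and after all
#: preprocessing steps, across the same survey (used by the attrition
#: worked example).
MEDIAN_VARIANTS_INITIAL = 5_509_545
MEDIAN_VARIANTS_FINAL = 3_894_315


def load_pediatric_survey_counts() -> pd.DataFrame:
    """The packaged per-disease count table as a DataFrame."""
    resource = importlib.resources.files("chtrio.data").joinpath(
        "pediatric_survey_counts.tsv"
    )
    with resource.open() as handle:
        return pd.read_csv(handle, sep="\t")


def pediatric_survey_summaries() -> list[DiseaseSummary]:
    """The packaged counts as :class:`DiseaseSummary` objects, ready for
    pooling and percent-increase computation."""
    frame = load_pediatric_survey_counts()
    summaries = []
    for row in frame.itertuples(index=False):
        summaries.append(
            DiseaseSummary(
                disease=row.disease,
                cohort_size=int(row.cohort_size),
                n_genes_ch_initial=int(row.genes_ch_initial),
                n_genes_ch_filtered=int(row.genes_ch_filtered),
                n_samples_ch_initial=int(row.samples_ch_initial),
                n_samples_ch_filtered=int(row.samples_ch_filtered),
                n_genes_ha_initial=int(row.genes_ha_initial),
                n_genes_ha_filtered=int(row.genes_ha_filtered),
                n_samples_ha_initial=int(row.samples_ha_initial),
                n_samples_ha_filtered=int(row.samples_ha_filtered),
                n_unique_ch_samples=int(row.unique_ch_samples),
                n_unique_ch_genes=int(row.unique_ch_genes),
            )
        )
    return summaries
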