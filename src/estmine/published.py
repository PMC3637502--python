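"""Published reference values for the Panax ginseng EST survey.

These are the printed tables of the original four-tissue 454 study: the 14
candidate miRNA rows (mature sequence, arm, GC%, precursor length, |MFE|,
MFEI, source read), the SSR motif-length x repeat-number count matrix, and
the assembly totals.  They serve as desk-scale *inputs* for the arithmetic
checks in the test-suite and the analysis scripts; nothing in the package
derives its behaviour from them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Assembly span of the unigene set (total coverage, bases).
ASSEMBLY_TOTAL_BASES = 75_621_996

#: Unigene count (contigs + singletons).
N_UNIGENES = 178_145

#: Total perfect SSRs reported from the unigene set.
N_SSRS = 13_044

#: Published SSR density, SSRs per Mb of assembly.
SSR_DENSITY_PER_MB = 172.5

#: Unigenes private to each tissue and shared by all four (Venn figures).
TISSUE_PRIVATE_UNIGENES = {"root": 45_849, "stem": 6_172, "leaf": 4_041, "flower": 3_273}
SHARED_ALL_TISSUES = 50_957

REPEAT_NUMBER_BINS = ("4", "5", "6", "7", "8", "9", "10", ">10")


def _data_path(name: str):
    return resources.files("estmine.data").joinpath(name)


def candidate_mirna_table() -> pd.DataFrame:
    """The 14 published candidate-miRNA rows as a DataFrame."""
    with resources.as_file(_data_path("panax_candidate_mirnas.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return df


def ssr_repeat_matrix() -> pd.DataFrame:
    """Published SSR counts by motif length (2-6) x repeat-number bin."""
    with resources.as_file(_data_path("panax_ssr_repeat_matrix.tsv")) as p:
        df = pd.read_csv(p, sep="\t", index_col="motif_len")
    df.columns = list(REPEAT_NUMBER_BINS)
    return df
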