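"""Packaged reference tables.

``load_common_breakpoints`` returns the published list of 80 recurrent
breakpoint regions from the 67-sample myeloma aCGH cohort, with their LINE-1
densities (elements per 100,000 bp) and break frequencies (percent of the
cohort contributing a breakpoint).  Published coordinates are 1-based
inclusive; they are converted to the package's 0-based half-open convention
unless ``raw=True``.
"""

from importlib import resources

import pandas as pd

CBP_COHORT_SIZE = 67
CBP_MIN_SUPPORT = 4


def load_common_breakpoints(raw: bool = False) -> pd.DataFrame:
    with resources.files("line1mm.data").joinpath("common_breakpoints.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    df["gene"] = df["gene"].fillna("")
    if not raw:
        df["start"] = df["start"] - 1
    return df
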