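"""The published 50-gene injection-screen mortality table and summaries.

The candidate lethal genes came from a large-scale dsRNA injection screen in
the model beetle *Tribolium castaneum*; the packaged table records mean %
mortality (three replicates, 150 nl of 250 ng/ul dsRNA, 14 days post
injection) for each of the 50 candidates, alongside the paired
*D. v. virgifera* diet-overlay outcome.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_DATA = "tribolium_injection_mortality.tsv"


def load_injection_screen() -> pd.DataFrame:
    """The packaged 50-gene injection-screen table as a DataFrame."""
    ref = resources.files("trigger_forge.data").joinpath(_DATA)
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    if df.gene.duplicated().any():
        raise ValueError("duplicate gene rows in the injection screen table")
    return df


def high_mortality_summary(
    df: pd.DataFrame | None = None, threshold_pct: float = 90.0
) -> dict[str, float]:
    """Count genes whose injection mortality exceeds a threshold.

    Returns the gene counts and the fraction (percent) of the screen above
    the threshold — the headline screen statistic.
    """
    if df is None:
        df = load_injection_screen()
    above = int((df.tc_mortality_pct > threshold_pct).sum())
    total = int(len(df))
    return {
        "n_total": total,
        "n_above": above,
        "fraction_pct": 100.0 * above / total,
        "threshold_pct": threshold_pct,
    }
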