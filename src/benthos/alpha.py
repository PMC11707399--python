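"""Alpha-diversity indices per analysis unit (site or pooled group).

Eight indices: species richness S, total abundance Sa (ind km^-2), total
biomass Sb (kg km^-2), Shannon-Wiener H', Margalef d, Pielou J', Simpson
diversity D = 1 - sum p^2 and inverse Simpson D' = 1 / sum p^2. Proportions
p_i are taken over species with positive abundance. The Shannon log base
defaults to 2 (marine-survey convention) and J' uses the same base, keeping
J' in [0, 1]; Margalef uses the natural log of total abundance.

Undefined cases (all-zero unit, single species for J') carry NaN, never a
silent zero.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .core_io import SampleTable

ALPHA_INDICES = ("S", "Sa", "Sb", "H", "d", "J", "D", "Dinv")


def alpha_record(
    abundance_row,
    biomass_row=None,
    log_base: float = 2.0,
) -> dict:
    """The eight alpha indices for one unit's abundance (and biomass) row."""
    x = np.asarray(abundance_row, float)
    if (x < 0).any():
        raise ValueError("negative abundance")
    pos = x[x > 0]
    s = int(pos.size)
    sa = float(x.sum())
    sb = float(np.asarray(biomass_row, float).sum()) if biomass_row is not None else math.nan
    rec = {"S": s, "Sa": sa, "Sb": sb, "H": math.nan, "d": math.nan,
           "J": math.nan, "D": math.nan, "Dinv": math.nan}
    if s == 0:
        return rec
    p = pos / pos.sum()
    h = float(-(p * np.log(p)).sum() / math.log(log_base))
    simpson_conc = float((p**2).sum())
    rec["H"] = h
    rec["D"] = 1.0 - simpson_conc
    rec["Dinv"] = 1.0 / simpson_conc
    rec["d"] = 0.0 if s == 1 else ((s - 1) / math.log(sa) if sa > 1 else math.nan)
    if s >= 2:
        rec["J"] = h / (math.log(s) / math.log(log_base))
    return rec


def alpha_table(
    abundance: SampleTable,
    biomass: SampleTable | None = None,
    log_base: float = 2.0,
) -> pd.DataFrame:
    """Per-site table of the eight alpha indices."""
    biom = biomass.data if biomass is not None else None
    rows = {}
    for site in abundance.sites:
        brow = biom.loc[site] if biom is not None else None
        rows[site] = alpha_record(abundance.data.loc[site], brow, log_base)
    df = pd.DataFrame.from_dict(rows, orient="index")[list(ALPHA_INDICES)]
    df.index.name = "site"
    df.attrs["log_base"] = log_base
    return df
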