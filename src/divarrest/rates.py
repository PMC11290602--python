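"""Stem-age diversification rates and equal-count quantile binning.

The per-family rate is the classic stem-age estimator r = ln(N) / t, with N
the family's extant species richness and t its stem age in Myr.  It assumes
no extinction (epsilon = 0) and is known to be biased, but it requires only
a richness count and a stem age, which makes it usable on family-level trees
with unresolved or imputed terminal structure.  Families are then ranked by
rate and cut into k equal-count bins ("quantiles"; k = 5 by default), bin 1
holding the lowest rates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError
from .treeio import FamilyTable

DEFAULT_K = 5


def diversification_rate(n_species, stem_age):
    """Stem-age diversification rate ln(N)/t in 1/Myr.

    Accepts scalars or array-likes.  Monotone increasing in ``n_species``
    and decreasing in ``stem_age``; N = 1 gives exactly 0 for any age.
    """
    n = np.asarray(n_species, dtype=float)
    t = np.asarray(stem_age, dtype=float)
    if np.any(n < 1):
        raise DomainError("n_species must be >= 1")
    if np.any(t <= 0):
        raise DomainError("stem_age must be > 0")
    r = np.log(n) / t
    return float(r) if r.ndim == 0 else r


def assign_quantiles(rates: pd.Series, k: int = DEFAULT_K) -> pd.Series:
    """Cut families into ``k`` equal-count rate bins (1 = lowest rates).

    Families are sorted ascending by ``(rate, family name)`` — the name is
    the deterministic tie-break — and split into consecutive bins.  When
    ``n mod k = m != 0`` the lowest-index bins take the extra members, so
    sizes are ceil(n/k) for bins 1..m and floor(n/k) after.

    Returns an integer Series aligned to the input index.
    """
    n = len(rates)
    if n < k:
        raise ConfigurationError(f"need at least {k} families, got {n}")
    order = rates.rename("rate").reset_index()
    order.columns = ["family", "rate"]
    order = order.sort_values(["rate", "family"], kind="mergesort")
    base, m = divmod(n, k)
    sizes = [base + 1] * m + [base] * (k - m)
    labels = np.repeat(np.arange(1, k + 1), sizes)
    out = pd.Series(labels, index=order["family"].values, name="quantile")
    return out.reindex(rates.index).astype(int)


def make_rate_table(family_table: FamilyTable, k: int = DEFAULT_K) -> pd.DataFrame:
    """Build the family,n_species,stem_age,rate,quantile table."""
    if family_table.n_species is None:
        raise ConfigurationError("family table has no richness column")
    df = family_table.to_frame().set_index("family")
    df["rate"] = diversification_rate(df["n_species"].values, df["stem_age"].values)
    df["quantile"] = assign_quantiles(df["rate"], k=k)
    return df.reset_index()


def quantile_members(rate_table: pd.DataFrame) -> dict[int, list[str]]:
    """Map quantile index -> sorted member family names."""
    return {
        int(q): sorted(g["family"])
        for q, g in rate_table.groupby("quantile", sort=True)
    }
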