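"""Mismatch-repair length dependence of prime insertion.

MMR recognizes and excises short (< ~13 nt) heteroduplex insertions before
the nicked strand is re-ligated, so losing MMR (e.g. MLH1 knockout) boosts
short insertions far more than long ones. The per-insert fold change
between MMR-deficient and MMR-proficient screens is modelled
phenomenologically as

    ratio(L) = a * exp(-b * L) + 1

with a > 0 the fold-scale and b > 0 the per-nt decay: the fold change at
L = 1 is a*exp(-b) + 1 and each additional nucleotide shrinks the MMR
benefit by 1 - exp(-b).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

MMR_INSENSITIVE_MIN_LEN = 14  # inserts > 13 nt escape MMR


@dataclass(frozen=True)
class MMRFit:
    a: float  # fold-scale, dimensionless, > 0
    b: float  # per-nt decay, 1/nt, > 0
    variance_explained: float

    @property
    def fold_change_1nt(self) -> float:
        return self.a * np.exp(-self.b) + 1.0

    @property
    def per_nt_drop(self) -> float:
        """Fractional drop of the MMR effect per additional nucleotide."""
        return 1.0 - np.exp(-self.b)

    def ratio(self, length) -> np.ndarray:
        return self.a * np.exp(-self.b * np.asarray(length, dtype=float)) + 1.0

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "fold_change_1nt": float(self.fold_change_1nt),
            "per_nt_drop_pct": float(100 * self.per_nt_drop),
            "variance_explained": self.variance_explained,
        }


def scale_genotypes(
    wt: pd.DataFrame, ko: pd.DataFrame, lengths: dict
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Remove the screen batch factor between WT and knockout tables.

    The knockout table is multiplied by a single scalar so that the mean
    efficiencies over shared inserts longer than 13 nt (not affected by
    MMR) are identical. Returns (wt, scaled ko, scale factor).
    """
    shared = set(wt["insert_id"]) & set(ko["insert_id"])
    long_ids = {i for i in shared if lengths[i] >= MMR_INSENSITIVE_MIN_LEN}
    if not long_ids:
        raise ValueError("no shared inserts > 13 nt to anchor genotype scaling")
    m_wt = wt[wt["insert_id"].isin(long_ids)]["efficiency"].mean()
    m_ko = ko[ko["insert_id"].isin(long_ids)]["efficiency"].mean()
    scale = m_wt / m_ko
    ko_scaled = ko.copy()
    ko_scaled["efficiency"] = ko_scaled["efficiency"] * scale
    return wt, ko_scaled, float(scale)


def fold_changes(
    wt: pd.DataFrame, ko: pd.DataFrame, lengths: dict
) -> pd.DataFrame:
    """Per-insert KO/WT efficiency ratios after genotype scaling."""
    wt2, ko2, _ = scale_genotypes(wt, ko, lengths)
    merged = wt2.merge(ko2, on="insert_id", suffixes=("_wt", "_ko"))
    merged = merged[merged["efficiency_wt"] > 0]
    out = pd.DataFrame(
        {
            "insert_id": merged["insert_id"],
            "length": merged["insert_id"].map(lengths),
            "ratio": merged["efficiency_ko"] / merged["efficiency_wt"],
        }
    )
    return out


def fit_mmr_exponential(ratios, lengths) -> MMRFit:
    """Nonlinear least squares of ratio = a*exp(-b*L) + 1 on the ratio scale.

    Initialized at a = max(ratio) - 1, b = 0.5 and bounded to
    a in (0, 1e3], b in (0, 5]. Needs >= 10 (length, ratio) pairs.
    """
    r = np.asarray(ratios, dtype=float)
    L = np.asarray(lengths, dtype=float)
    if r.shape != L.shape or r.size < 10:
        raise ValueError("need >= 10 aligned (length, ratio) pairs")

    def model(x, a, b):
        return a * np.exp(-b * x) + 1.0

    a0 = max(float(np.nanmax(r)) - 1.0, 1e-3)
    try:
        popt, _ = curve_fit(
            model, L, r, p0=[a0, 0.5],
            bounds=([1e-9, 1e-9], [1e3, 5.0]), maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover
        raise RuntimeError(f"MMR exponential fit failed to converge: {exc}") from exc
    a, b = map(float, popt)
    resid = r - model(L, a, b)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return MMRFit(a=a, b=b, variance_explained=r2)
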