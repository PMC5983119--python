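"""Classification of significant splicing events into skiptic / cryptic /
alternative-shift categories, the permutation control, and two-dataset
concordance.

A *skiptic* exon is constitutively included in wild type (WT PSI above
``psi_hi``, default 0.95) and significantly skipped in the mutant (dPSI below
-``dpsi_min``, default 0.05); a *cryptic* exon is constitutively repressed in
WT (PSI below ``psi_lo``, default 0.05) and significantly included in the
mutant (dPSI above +``dpsi_min``).  Any other FDR-significant event is an
alternative-splicing shift.  A stricter preset (``dpsi_min=0.1``) is exposed
for volcano-plot-style definitions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .core_io import ConfigurationError, SampleSheet
from .splicing import PsiTable, diff_splicing

DEFAULT_FDR = 0.01
DEFAULT_PSI_HI = 0.95
DEFAULT_PSI_LO = 0.05
DEFAULT_DPSI_MIN = 0.05

#: the stricter threshold preset (|dPSI| > 0.1)
STRICT_DPSI_MIN = 0.1

CATEGORIES = ("skiptic", "cryptic", "alt_shift", "none")


def exclusion_fold_change(psi_wt: float, psi_mut: float, pseudocount: float = 0.001) -> float:
    """Mutant / WT exclusion-fraction ratio, pseudocount-guarded."""
    if not (0 <= psi_wt <= 1 and 0 <= psi_mut <= 1):
        raise ValueError("PSI values must lie in [0, 1]")
    return ((1.0 - psi_mut) + pseudocount) / ((1.0 - psi_wt) + pseudocount)


def call_events(
    results: pd.DataFrame,
    fdr_cut: float = DEFAULT_FDR,
    psi_hi: float = DEFAULT_PSI_HI,
    psi_lo: float = DEFAULT_PSI_LO,
    dpsi_min: float = DEFAULT_DPSI_MIN,
    pseudocount: float = 0.001,
) -> pd.DataFrame:
    """Assign each differential-splicing result a category.

    Among FDR-significant events: skiptic if WT PSI > psi_hi and
    dPSI < -dpsi_min; cryptic if WT PSI < psi_lo and dPSI > +dpsi_min;
    alt_shift otherwise.  Non-significant events are category "none".
    """
    for name, v in [("fdr_cut", fdr_cut), ("psi_hi", psi_hi), ("psi_lo", psi_lo), ("dpsi_min", dpsi_min)]:
        if not (0 < v < 1):
            raise ConfigurationError(f"{name} must lie in (0, 1), got {v}")
    sig = (results["fdr"] < fdr_cut) & results["tested"]
    skiptic = sig & (results["psi_ref"] > psi_hi) & (results["dpsi"] < -dpsi_min)
    cryptic = sig & (results["psi_ref"] < psi_lo) & (results["dpsi"] > dpsi_min)
    category = np.where(
        skiptic, "skiptic", np.where(cryptic, "cryptic", np.where(sig, "alt_shift", "none"))
    )
    efc = [
        exclusion_fold_change(w, m, pseudocount)
        if np.isfinite(w) and np.isfinite(m)
        else np.nan
        for w, m in zip(results["psi_ref"], results["psi_mut"])
    ]
    out = results[["event_id", "gene_id", "event_class", "psi_ref", "dpsi", "fdr", "z"]].copy()
    out["category"] = category
    out["exclusion_fold_change"] = efc
    return out


@dataclass
class PermutationSummary:
    n_permutations: int
    skiptic_counts: np.ndarray  # per permutation
    cryptic_counts: np.ndarray
    observed_skiptic: int
    observed_cryptic: int

    @property
    def empirical_p_skiptic(self) -> float:
        k = int((self.skiptic_counts >= self.observed_skiptic).sum())
        return (1 + k) / (self.n_permutations + 1)

    @property
    def empirical_p_cryptic(self) -> float:
        k = int((self.cryptic_counts >= self.observed_cryptic).sum())
        return (1 + k) / (self.n_permutations + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "permutation": np.arange(1, self.n_permutations + 1),
                "skiptic_count": self.skiptic_counts,
                "cryptic_count": self.cryptic_counts,
            }
        )


def _distinct_assignments(sheet: SampleSheet):
    """All distinct non-identity condition-label assignments (whole-sample
    label permutations)."""
    conds = sheet.conditions
    if len(conds) != 2:
        raise ConfigurationError("permutation control needs exactly 2 conditions")
    a, b = conds
    ids = sheet.sample_ids
    n_a = len(sheet.condition_samples(a))
    identity = frozenset(sheet.condition_samples(a))
    out = []
    for combo in combinations(ids, n_a):
        fs = frozenset(combo)
        if fs == identity:
            continue
        out.append({s: (a if s in fs else b) for s in ids})
    return out


def permutation_control(
    psi_table: PsiTable,
    sheet: SampleSheet,
    n_perm: int = 50,
    seed: int = 0,
    fdr_cut: float = DEFAULT_FDR,
    psi_hi: float = DEFAULT_PSI_HI,
    psi_lo: float = DEFAULT_PSI_LO,
    dpsi_min: float = DEFAULT_DPSI_MIN,
    ref_condition=None,
) -> PermutationSummary:
    """Re-run the differential test and category calls under random
    condition-label permutations, yielding the null distribution of skiptic
    and cryptic call counts and empirical p-values for the observed counts.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    pool = _distinct_assignments(sheet)
    if len(pool) < n_perm:
        warnings.warn(
            f"only {len(pool)} distinct non-identity permutations available; "
            f"running all of them"
        )
        chosen = pool
    else:
        idx = rng.choice(len(pool), size=n_perm, replace=False)
        chosen = [pool[i] for i in sorted(idx)]

    def _counts(res):
        calls = call_events(res, fdr_cut, psi_hi, psi_lo, dpsi_min)
        vc = calls["category"].value_counts()
        return int(vc.get("skiptic", 0)), int(vc.get("cryptic", 0))

    obs_s, obs_c = _counts(diff_splicing(psi_table, sheet, ref_condition))
    sk, cr = [], []
    for assignment in chosen:
        perm_sheet = sheet.relabelled(assignment)
        s, c = _counts(diff_splicing(psi_table, perm_sheet, ref_condition))
        sk.append(s)
        cr.append(c)
    return PermutationSummary(
        len(chosen), np.array(sk), np.array(cr), obs_s, obs_c
    )


def two_way_comparison(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    fdr_cut: float = 0.1,
) -> dict:
    """Concordance of signed z-scores between two datasets over events
    significant in both (shared annotation / event ids required)."""
    a = results_a[results_a["fdr"] < fdr_cut]
    b = results_b[results_b["fdr"] < fdr_cut]
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        warnings.warn("no shared significant events between datasets")
        return {
            "n_shared_significant": 0,
            "concordance": math.nan,
            "quadrants": {},
            "pairs": pd.DataFrame(columns=["z_a", "z_b"]),
        }
    za = a.loc[shared, "z"].to_numpy()
    zb = b.loc[shared, "z"].to_numpy()
    same = np.sign(za) == np.sign(zb)
    quadrants = {
        "++": int(((za > 0) & (zb > 0)).sum()),
        "+-": int(((za > 0) & (zb <= 0)).sum()),
        "-+": int(((za <= 0) & (zb > 0)).sum()),
        "--": int(((za <= 0) & (zb <= 0)).sum()),
    }
    return {
        "n_shared_significant": int(len(shared)),
        "concordance": float(same.mean()),
        "quadrants": quadrants,
        "pairs": pd.DataFrame({"z_a": za, "z_b": zb}, index=shared),
    }
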