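"""Kinetic classification of ligands by calcium-transient dwell time.

Responding ligands fall into dwell-time (DT) classes: short (DT < 15 s),
long (25 s < DT <= 30 s) and very long (DT > 30 s). The 15-25 s gap the
class bounds leave open is labelled ``intermediate`` so classification is a
total function; ``very_long`` takes precedence over ``long`` where the
published bounds overlap (> 30 s is a subset of > 25 s).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .stats import mann_whitney_u

__all__ = ["KINETIC_CLASSES", "classify_dwell", "compare_ligands"]

KINETIC_CLASSES = ("short", "intermediate", "long", "very_long")

SHORT_MAX = 15.0      # s, exclusive upper bound of the short class
LONG_MIN = 25.0       # s, exclusive lower bound of the long class
VERY_LONG_MIN = 30.0  # s, exclusive lower bound of the very-long class


def classify_dwell(dwell: float) -> str:
    """Assign the kinetic class for one dwell time (s)."""
    dwell = float(dwell)
    if not np.isfinite(dwell) or dwell < 0:
        raise ValueError("dwell time must be finite and non-negative")
    if dwell > VERY_LONG_MIN:
        return "very_long"
    if dwell > LONG_MIN:
        return "long"
    if dwell < SHORT_MAX:
        return "short"
    return "intermediate"


def compare_ligands(groups: dict, reference: str,
                    correction: str | None = None) -> pd.DataFrame:
    """Pairwise Mann-Whitney comparisons of per-ligand dwell-time samples.

    Every ligand is compared against ``reference``, then all remaining pairs
    are compared in descending order of their median dwell time. P-values are
    two-sided and uncorrected by default (``correction="bonferroni"`` or
    ``"holm"`` applies a family-wise adjustment over the table).

    Returns a DataFrame with columns ligand_a, ligand_b, U, p.
    """
    if reference not in groups:
        raise ValueError(f"reference ligand {reference!r} not in groups")
    for name, sample in groups.items():
        if len(sample) < 3:
            raise ValueError(f"group {name!r} has fewer than 3 observations")

    rows = []
    others = [g for g in groups if g != reference]
    for other in others:
        res = mann_whitney_u(groups[reference], groups[other])
        rows.append((reference, other, res.statistic, res.p_value))
    by_median = sorted(others, key=lambda g: -float(np.median(groups[g])))
    for a, b in itertools.combinations(by_median, 2):
        res = mann_whitney_u(groups[a], groups[b])
        rows.append((a, b, res.statistic, res.p_value))

    df = pd.DataFrame(rows, columns=["ligand_a", "ligand_b", "U", "p"])
    if correction:
        df["p"] = _adjust(df["p"].to_numpy(), correction)
    return df


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    m = p.size
    if method == "bonferroni":
        return np.minimum(1.0, p * m)
    if method == "holm":
        order = np.argsort(p)
        adj = np.empty_like(p)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(1.0, running)
        return adj
    raise ValueError(f"unknown correction {method!r}")
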