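"""Within-spot cell-type co-occurrence scoring on deconvolved spot tables.

For two cell-type proportions κ1, κ2 inside one spatial spot the
co-occurrence score is

    C(κ1, κ2) = (κ1 + κ2) * exp(-3 * (κ1 - κ2)**2)

which grows with the total abundance of the pair and is largest when the two
proportions are balanced (close to the κ1 = κ2 axis); C ranges over [0, 2].
Group comparisons use the difference of group mean scores per pair with a
label-permutation p-value.  Within- and next-spot Pearson correlations of
the proportion columns complete the module.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "cooccurrence_score",
    "spot_adjacency",
    "within_spot_correlation",
    "next_spot_correlation",
    "CooccurrenceModel",
    "CooccurrenceResults",
]

META_COLS = ("spot_id", "x", "y", "group")


def cooccurrence_score(k1, k2):
    """C(κ1, κ2) = (κ1 + κ2) · exp(−3 (κ1 − κ2)²), elementwise."""
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    if np.any((k1 < 0) | (k1 > 1) | (k2 < 0) | (k2 > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = (k1 + k2) * np.exp(-3.0 * (k1 - k2) ** 2)
    return float(out) if out.ndim == 0 else out


def _proportion_cols(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLS]


def _validate_table(table: pd.DataFrame, atol: float = 1e-6) -> list[str]:
    types = _proportion_cols(table)
    P = table[types].to_numpy(dtype=float)
    if np.any((P < -atol) | (P > 1 + atol)):
        raise ValueError("spot proportions outside [0, 1]")
    if len(types) and np.any(np.abs(P.sum(axis=1) - 1.0) > atol):
        raise ValueError("spot proportions must sum to 1 per row")
    return types


def spot_adjacency(table: pd.DataFrame, scale: float = 1.5) -> np.ndarray:
    """Adjacent spot pairs: centers within ``scale`` x the median NN distance.

    Captures the 6-neighbor packing of a hexagonal spot grid while staying
    robust to occasional missing spots.  Returns an (m, 2) array of row-index
    pairs (i < j). Computed within one tissue/group at a time by the caller.
    """
    xy = table[["x", "y"]].to_numpy(dtype=float)
    if len(xy) < 2:
        return np.empty((0, 2), dtype=int)
    tree = cKDTree(xy)
    nn_dist, _ = tree.query(xy, k=2)
    cutoff = scale * float(np.median(nn_dist[:, 1]))
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    return pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]


def within_spot_correlation(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson ρ between cell-type proportion columns across spots.

    Zero-variance columns yield missing entries (pandas convention).
    """
    types = _validate_table(table)
    if len(table) < 3:
        raise ValueError("need at least 3 spots for correlations")
    return table[types].corr(method="pearson")


def next_spot_correlation(
    table: pd.DataFrame, adjacency: np.ndarray | None = None, scale: float = 1.5
) -> pd.DataFrame:
    """Pearson ρ between κ_t in a spot and κ_u in its adjacent spots.

    Correlations are taken over all ordered adjacent pairs (both directions),
    which makes the resulting type x type matrix symmetric.  Isolated spots
    simply contribute no pairs; a table with no adjacent pairs is an error.
    """
    types = _validate_table(table)
    if adjacency is None:
        adjacency = spot_adjacency(table, scale=scale)
    if len(adjacency) == 0:
        raise ValueError("no adjacent spot pairs (all spots isolated)")
    P = table[types].to_numpy(dtype=float)
    a = np.concatenate([adjacency[:, 0], adjacency[:, 1]])
    b = np.concatenate([adjacency[:, 1], adjacency[:, 0]])
    A, B = P[a], P[b]
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    num = A.T @ B
    sa = np.sqrt((A**2).sum(axis=0))
    sb = np.sqrt((B**2).sum(axis=0))
    denom = np.outer(sa, sb)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)
    return pd.DataFrame(rho, index=types, columns=types)


@dataclass
class CooccurrenceResults:
    """Per-spot pair scores, per-group summaries and the group differential."""

    per_spot: pd.DataFrame  # long: spot_id, group, type_a, type_b, C
    group_means: pd.DataFrame  # (type_a, type_b) x group
    differential: pd.DataFrame  # pair, diff = mean(g1) - mean(g2), p_perm
    group_pair: tuple[str, str]
    n_permutations: int

    def top_pairs(self, n: int = 10) -> pd.DataFrame:
        return self.differential.nlargest(n, "diff")

    def summary(self) -> str:
        g1, g2 = self.group_pair
        lines = [
            "Within-spot co-occurrence analysis",
            f"  spots: {self.per_spot['spot_id'].nunique()}   "
            f"pairs: {len(self.differential)}",
            f"  differential: mean C in {g1!r} minus mean C in {g2!r} "
            f"({self.n_permutations} label permutations)",
            "  top differential pairs:",
        ]
        for _, r in self.top_pairs(5).iterrows():
            lines.append(
                f"    {r['type_a']} - {r['type_b']}: diff={r['diff']:+.4f} "
                f"p={r['p_perm']:.4f}"
            )
        return "\n".join(lines)


class CooccurrenceModel:
    """Co-occurrence model for one spot-proportion table with group labels.

    Parameters
    ----------
    table : DataFrame with columns spot_id, x, y, group and one proportion
        column per cell type (rows summing to 1).
    group_pair : the two group labels to contrast, ``(disease, control)``;
        the differential is disease mean minus control mean.
    """

    def __init__(self, table: pd.DataFrame, group_pair: tuple[str, str]):
        self.types = _validate_table(table)
        if len(self.types) < 2:
            warnings.warn("fewer than 2 cell types: no pairs, results will be empty")
        self.table = table.reset_index(drop=True)
        self.group_pair = tuple(group_pair)
        for g in self.group_pair:
            if (self.table["group"] == g).sum() == 0:
                raise ValueError(f"group {g!r} has 0 spots; differential undefined")

    def _pair_scores(self) -> tuple[list[tuple[str, str]], np.ndarray]:
        P = self.table[self.types].to_numpy(dtype=float)
        pairs = list(itertools.combinations(self.types, 2))
        cols = {t: j for j, t in enumerate(self.types)}
        C = np.column_stack(
            [cooccurrence_score(P[:, cols[a]], P[:, cols[b]]) for a, b in pairs]
        )
        return pairs, C

    def fit(self, n_permutations: int = 1000, seed: int = 0) -> CooccurrenceResults:
        if len(self.types) < 2:
            empty_diff = pd.DataFrame(columns=["type_a", "type_b", "diff", "p_perm"])
            return CooccurrenceResults(
                per_spot=pd.DataFrame(
                    columns=["spot_id", "group", "type_a", "type_b", "C"]
                ),
                group_means=pd.DataFrame(),
                differential=empty_diff,
                group_pair=self.group_pair,
                n_permutations=n_permutations,
            )
        pairs, C = self._pair_scores()
        groups = self.table["group"].to_numpy()
        g1, g2 = self.group_pair
        in1, in2 = groups == g1, groups == g2

        obs = C[in1].mean(axis=0) - C[in2].mean(axis=0)

        rng = np.random.default_rng(seed)
        sub = np.flatnonzero(in1 | in2)
        lab = in1[sub]
        Csub = C[sub]
        n1 = int(lab.sum())
        exceed = np.zeros(len(pairs), dtype=int)
        for _ in range(n_permutations):
            perm = rng.permutation(lab.size)
            p1 = perm[:n1]
            p2 = perm[n1:]
            diff = Csub[p1].mean(axis=0) - Csub[p2].mean(axis=0)
            exceed += np.abs(diff) >= np.abs(obs) - 1e-12
        p_perm = (exceed + 1) / (n_permutations + 1)

        long = self.table[["spot_id", "group"]].copy()
        per_spot = pd.concat(
            [
                long.assign(type_a=a, type_b=b, C=C[:, j])
                for j, (a, b) in enumerate(pairs)
            ],
            ignore_index=True,
        )
        gm_rows = []
        for j, (a, b) in enumerate(pairs):
            row = {"type_a": a, "type_b": b}
            for g in pd.unique(groups):
                row[str(g)] = C[groups == g, j].mean()
            gm_rows.append(row)
        group_means = pd.DataFrame(gm_rows).set_index(["type_a", "type_b"])
        differential = pd.DataFrame(
            {
                "type_a": [a for a, _ in pairs],
                "type_b": [b for _, b in pairs],
                "diff": obs,
                "p_perm": p_perm,
            }
        )
        return CooccurrenceResults(
            per_spot=per_spot,
            group_means=group_means,
            differential=differential,
            group_pair=self.group_pair,
            n_permutations=n_permutations,
        )
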