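"""Continuous piecewise-linear (segmented) regression with AIC model selection.

Fits a ranked curve ``y`` against its rank ``x = 1..n`` with up to
``max_breakpoints`` knots, searching breakpoint positions exhaustively over
integer candidate ranks.  Model selection among breakpoint counts
``b = 0..max_breakpoints`` uses the Gaussian-likelihood AIC

    AIC = n * ln(RSS / n) + 2 * p,      p = 2 + 2 * b

where the parameter count charges two per breakpoint (knot position plus
slope change) on top of intercept and base slope.  Selection follows the
usual parsimony convention: the smallest breakpoint count whose AIC lies
within ``parsimony_margin`` (default 10, the conventional "essentially no
support" gap) of the minimum wins.  A genuine kink at workable
signal-to-noise is worth hundreds of AIC units, while the exhaustive search
can scrape only a handful of units out of pure noise, so the margin
suppresses spurious knots without costing real ones; on exact ties (e.g. a
noiseless straight line, where every model reaches the RSS floor) the
fewest-parameter model is selected.

The search is exact over the candidate grid: for every admissible breakpoint
combination the least-squares problem is solved through its normal equations,
assembled from precomputed inner products of the hinge basis
``max(x - c, 0)`` so that millions of candidate models stay affordable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SegmentedRegression", "SegmentedRegressionResults"]

# fits are treated as exact once RSS falls below a relative floor: near zero,
# RSS values computed through the normal equations differ only by cancellation
# noise, which n*ln(RSS/n) would amplify into spurious model preferences.
# The floor is identical across models, so ties on perfect fits are broken
# purely by the parameter penalty.
_RSS_FLOOR_REL = 1e-10


def _default_min_seg(n: int) -> int:
    return max(3, int(np.ceil(0.02 * n)))


@dataclass
class SegmentedRegressionResults:
    """Chosen piecewise-linear model and the per-candidate-count diagnostics.

    Attributes
    ----------
    n_breakpoints : number of knots in the AIC-selected model.
    breakpoints : knot positions on the rank axis (sorted, possibly empty).
    params : ``[intercept, slope, dslope_1, ..., dslope_b]`` of the hinge basis.
    aic : AIC of the selected model.
    aic_by_count : AIC of the best model for each candidate breakpoint count.
    rss : residual sum of squares of the selected model.
    flagged : True when no breakpoint model was admissible (curve too short)
        and the straight-line fit was returned by necessity.
    """

    n_breakpoints: int
    breakpoints: np.ndarray
    params: np.ndarray
    aic: float
    aic_by_count: dict[int, float]
    rss: float
    nobs: int
    flagged: bool = False
    x: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)

    @property
    def fittedvalues(self) -> np.ndarray:
        return _design(self.x, self.breakpoints) @ self.params

    @property
    def resid(self) -> np.ndarray:
        return self.y - self.fittedvalues

    def predict(self, x: np.ndarray) -> np.ndarray:
        return _design(np.asarray(x, dtype=float), self.breakpoints) @ self.params

    def summary(self) -> str:
        lines = [
            "Segmented (piecewise-linear) regression",
            f"  nobs: {self.nobs}",
            f"  selected breakpoints: {self.n_breakpoints}"
            + (" (flagged: no admissible breakpoint model)" if self.flagged else ""),
            f"  breakpoint ranks: {np.round(self.breakpoints, 4).tolist()}",
            f"  params (intercept, slope, slope changes): "
            f"{np.round(self.params, 6).tolist()}",
            f"  RSS: {self.rss:.6g}   AIC: {self.aic:.4f}",
            "  AIC by breakpoint count: "
            + ", ".join(f"b={b}: {a:.3f}" for b, a in sorted(self.aic_by_count.items())),
        ]
        return "\n".join(lines)


def _design(x: np.ndarray, breakpoints: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(x), x]
    for c in np.atleast_1d(breakpoints):
        cols.append(np.maximum(x - c, 0.0))
    return np.column_stack(cols)


class SegmentedRegression:
    """Exhaustive-search segmented regression on a ranked curve.

    Parameters
    ----------
    y : 1-D array of responses, ordered by rank (ascending for the CTR use
        case, though ordering is the caller's contract).
    x : optional rank grid; defaults to ``1..n``. Must be strictly increasing.
    max_breakpoints : largest breakpoint count considered (0..3 typical).
    min_seg : minimum number of ranks between consecutive knots and between a
        knot and either end of the curve; defaults to ``max(3, 2% of n)``.
    parsimony_margin : AIC gap below which a simpler model is preferred over
        the minimum-AIC model; 0 reproduces strict minimum-AIC selection.
    """

    def __init__(
        self,
        y,
        x=None,
        max_breakpoints: int = 3,
        min_seg: int | None = None,
        parsimony_margin: float = 10.0,
    ):
        self.y = np.asarray(y, dtype=float).ravel()
        n = self.y.size
        if n < 2:
            raise ValueError("need at least 2 points to fit a line")
        if x is None:
            self.x = np.arange(1, n + 1, dtype=float)
        else:
            self.x = np.asarray(x, dtype=float).ravel()
            if self.x.size != n:
                raise ValueError("x and y lengths differ")
            if np.any(np.diff(self.x) <= 0):
                raise ValueError("rank grid must be strictly increasing")
        if max_breakpoints < 0:
            raise ValueError("max_breakpoints must be >= 0")
        self.max_breakpoints = int(max_breakpoints)
        self.min_seg = _default_min_seg(n) if min_seg is None else int(min_seg)
        if self.min_seg < 1:
            raise ValueError("min_seg must be >= 1")
        if parsimony_margin < 0:
            raise ValueError("parsimony_margin must be >= 0")
        self.parsimony_margin = float(parsimony_margin)

    # -- internal -----------------------------------------------------------

    def _candidates(self) -> np.ndarray:
        """Integer ranks admissible as knots: at least min_seg from each end."""
        n = self.y.size
        lo, hi = self.x[0] + self.min_seg, self.x[-1] - self.min_seg
        cand = self.x[(self.x >= lo) & (self.x <= hi)]
        return cand

    def _fit_b0(self) -> tuple[float, np.ndarray]:
        X = _design(self.x, np.empty(0))
        beta, *_ = np.linalg.lstsq(X, self.y, rcond=None)
        rss = float(np.sum((self.y - X @ beta) ** 2))
        return rss, beta

    def _search(self, b: int, cand: np.ndarray) -> tuple[float, np.ndarray, np.ndarray] | None:
        """Best RSS over all spacing-admissible b-subsets of cand.

        Normal equations are assembled from precomputed inner products of the
        basis vectors {1, x, hinge(c)} so the whole candidate batch is solved
        with one vectorized call.
        """
        m = cand.size
        if m < b:
            return None
        combos = np.array(list(itertools.combinations(range(m), b)), dtype=np.intp)
        if combos.size == 0:
            return None
        if b > 1:
            gaps = np.diff(cand[combos], axis=1)
            combos = combos[np.all(gaps >= self.min_seg, axis=1)]
            if combos.shape[0] == 0:
                return None

        x, y = self.x, self.y
        n = x.size
        hinges = np.maximum(x[None, :] - cand[:, None], 0.0)  # (m, n)
        # inner products with the fixed columns and the response
        h_1 = hinges.sum(axis=1)
        h_x = hinges @ x
        h_y = hinges @ y
        h_h = hinges @ hinges.T  # (m, m)
        s1, sx, sxx, sy, sxy = n, x.sum(), x @ x, y.sum(), x @ y
        yy = y @ y

        p = 2 + b
        M = combos.shape[0]
        best_rss, best_idx, best_beta = np.inf, None, None
        chunk = max(1, int(2_000_000 / (p * p)))
        for start in range(0, M, chunk):
            sub = combos[start : start + chunk]
            k = sub.shape[0]
            A = np.empty((k, p, p))
            rhs = np.empty((k, p))
            A[:, 0, 0] = s1
            A[:, 0, 1] = A[:, 1, 0] = sx
            A[:, 1, 1] = sxx
            rhs[:, 0] = sy
            rhs[:, 1] = sxy
            A[:, 0, 2:] = A[:, 2:, 0] = h_1[sub]
            A[:, 1, 2:] = A[:, 2:, 1] = h_x[sub]
            A[:, 2:, 2:] = h_h[sub[:, :, None], sub[:, None, :]]
            rhs[:, 2:] = h_y[sub]
            try:
                beta = np.linalg.solve(A, rhs[..., None])[..., 0]
            except np.linalg.LinAlgError:
                beta = np.linalg.pinv(A) @ rhs[..., None]
                beta = beta[..., 0]
            rss = yy - np.einsum("ij,ij->i", beta, rhs)
            i = int(np.argmin(rss))
            if rss[i] < best_rss:
                best_rss = float(rss[i])
                best_idx = sub[i]
                best_beta = beta[i]
        if best_idx is None:
            return None
        # numerical round-off can push a perfect fit slightly negative
        best_rss = max(best_rss, 0.0)
        return best_rss, cand[best_idx], best_beta

    # -- public -------------------------------------------------------------

    def fit(self) -> SegmentedRegressionResults:
        n = self.y.size
        rss0, beta0 = self._fit_b0()
        aic_by: dict[int, float] = {}
        models: dict[int, tuple[float, np.ndarray, np.ndarray]] = {}

        floor = _RSS_FLOOR_REL * max(float(self.y @ self.y), 1.0)

        def aic(rss: float, b: int) -> float:
            p = 2 + 2 * b
            return n * np.log(max(rss, floor) / n) + 2 * p

        aic_by[0] = aic(rss0, 0)
        models[0] = (rss0, np.empty(0), beta0)

        cand = self._candidates()
        any_bp_possible = False
        for b in range(1, self.max_breakpoints + 1):
            out = self._search(b, cand)
            if out is None:
                continue
            any_bp_possible = True
            rss, bps, beta = out
            aic_by[b] = aic(rss, b)
            models[b] = (rss, bps, beta)

        # simplest model within the parsimony margin of the AIC minimum;
        # margin 0 degenerates to strict lowest-AIC with ties to fewer knots
        aic_min = min(aic_by.values())
        best_b = min(b for b, a in aic_by.items() if a <= aic_min + self.parsimony_margin)
        rss, bps, beta = models[best_b]
        return SegmentedRegressionResults(
            n_breakpoints=best_b,
            breakpoints=np.asarray(bps, dtype=float),
            params=np.asarray(beta, dtype=float),
            aic=aic_by[best_b],
            aic_by_count=aic_by,
            rss=rss,
            nobs=n,
            flagged=(self.max_breakpoints > 0 and not any_bp_possible),
            x=self.x,
            y=self.y,
        )
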