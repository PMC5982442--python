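"""Permutation-based factorial inference for the monolith design.

Two-factor (treatment x land use) permutation ANOVA with sequential sums of
squares: main-effect p-values come from permuting the raw observations,
the interaction p-value from the Freedman-Lane scheme (permute residuals of
the additive main-effects fit, add them back to the additive fitted values,
refit and recompute the interaction F). Within-land-use drought effects use
a two-sample permutation test on the difference of means, which orders
permutations identically to the one-way F because the total sum of squares
is permutation-invariant.

Exhaustive enumeration replaces Monte-Carlo sampling automatically whenever
the number of distinct rearrangements does not exceed ``n_perm``; otherwise
p = (1 + #{T* >= T_obs}) / (1 + n_perm), so p can never drop below
1/(n_perm + 1).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PermTestResult",
    "two_way_perm_anova",
    "within_group_perm_test",
    "significance_stars",
]

_REL_EPS = 1e-12  # tolerance for >= comparisons, keeps p affine-invariant


@dataclass(frozen=True)
class PermTestResult:
    response: str
    occasion: str
    factor: str
    f_obs: float
    p_perm: float
    n_perm: int
    exhaustive: bool
    seed: int | None

    @property
    def stars(self) -> str:
        return significance_stars(self.p_perm)


def significance_stars(p: float) -> str:
    """Significance labels at the 0.001/0.01/0.05/0.1 levels."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "(*)"
    return "n.s."


def _dummies(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Indicator columns for levels 1..k-1 (level 0 absorbed by intercept)."""
    return (codes[:, None] == np.arange(1, n_levels)[None, :]).astype(float)


def _rss(q: np.ndarray, y2d: np.ndarray) -> np.ndarray:
    """Residual sum of squares of each column of y2d under the model whose
    thin-QR factor is q."""
    tot = np.einsum("ij,ij->j", y2d, y2d)
    proj = q.T @ y2d
    return tot - np.einsum("ij,ij->j", proj, proj)


def _seq_f(qs: list[np.ndarray], dfs: list[int], df_res: int, y2d: np.ndarray) -> list[np.ndarray]:
    """Sequential F statistics for each nested-model increment.

    ``qs`` are QR factors of the nested models (intercept-only first, full
    model last); ``dfs`` the incremental degrees of freedom. Zero-variance
    columns yield F = 0 by convention.
    """
    rss = [_rss(q, y2d) for q in qs]
    mse = rss[-1] / df_res
    # sums of squares below fp-cancellation noise (relative to ||y||^2)
    # count as exactly zero, so a constant response yields F = 0
    tol = 1e-9 * np.einsum("ij,ij->j", y2d, y2d) / y2d.shape[0]
    out = []
    for i, df in enumerate(dfs):
        ss = np.maximum(rss[i] - rss[i + 1], 0.0)
        f = np.zeros_like(ss)
        pos = mse > tol
        f[pos] = (ss[pos] / df) / mse[pos]
        f[~pos & (ss > tol)] = np.inf  # perfect fit with signal
        out.append(f)
    return out


def _perm_indices(rng: np.random.Generator, n: int, n_perm: int) -> tuple[np.ndarray, bool]:
    """Permutation index matrix (columns = permutations) and whether it is
    the exhaustive set."""
    if math.factorial(n) <= n_perm:
        idx = np.array(list(itertools.permutations(range(n))), dtype=np.intp).T
        return idx, True
    tiles = np.tile(np.arange(n, dtype=np.intp), (n_perm, 1))
    return rng.permuted(tiles, axis=1).T, False


def _p_value(stat_perm: np.ndarray, stat_obs: float, exhaustive: bool) -> float:
    thresh = stat_obs - _REL_EPS * abs(stat_obs)
    count = int(np.count_nonzero(stat_perm >= thresh))
    if exhaustive:
        return count / stat_perm.size
    return (count + 1) / (stat_perm.size + 1)


def two_way_perm_anova(
    y,
    a,
    b,
    n_perm: int = 4999,
    seed: int | None = None,
    response: str = "y",
    occasion: str = "",
    factor_names: tuple[str, str] = ("treatment", "land_use"),
) -> list[PermTestResult]:
    """Permutation ANOVA for a two-factor layout (balanced or not).

    Returns results for factor a, factor b and their interaction.
    """
    y = np.asarray(y, dtype=float)
    a_codes, a_levels = _codes(a)
    b_codes, b_levels = _codes(b)
    n = y.size
    if a_codes.size != n or b_codes.size != n:
        raise ValueError("y, a and b must have equal length")
    for name, levels in zip(factor_names, (a_levels, b_levels)):
        if len(levels) < 2:
            raise ValueError(f"factor {name!r} needs >= 2 levels")
    na, nb = len(a_levels), len(b_levels)
    cell_counts = np.zeros((na, nb), dtype=int)
    np.add.at(cell_counts, (a_codes, b_codes), 1)
    if np.any(cell_counts == 0):
        raise ValueError("empty cell: the interaction test needs every a x b cell filled")
    df_a, df_b = na - 1, nb - 1
    df_ab = df_a * df_b
    p_full = 1 + df_a + df_b + df_ab
    df_res = n - p_full
    if df_res < 1:
        raise ValueError(
            "no residual degrees of freedom; the interaction test needs >= 2 "
            "observations in some cells"
        )

    ones = np.ones((n, 1))
    xa = np.hstack([ones, _dummies(a_codes, na)])
    xb_cols = _dummies(b_codes, nb)
    xab = np.hstack([xa, xb_cols])
    inter = (xa[:, 1:, None] * xb_cols[:, None, :]).reshape(n, df_ab)
    xfull = np.hstack([xab, inter])
    qs = [np.linalg.qr(x)[0] for x in (ones, xa, xab, xfull)]
    dfs = [df_a, df_b, df_ab]

    f_obs = [float(f[0]) for f in _seq_f(qs, dfs, df_res, y[:, None])]

    rng = np.random.default_rng(seed)
    idx, exhaustive = _perm_indices(rng, n, n_perm)
    n_done = idx.shape[1]

    # main effects: permute raw observations
    y_perm = y[idx]
    f_perm_main = _seq_f(qs, dfs, df_res, y_perm)
    # interaction: Freedman-Lane on residuals of the additive fit
    coef, *_ = np.linalg.lstsq(xab, y, rcond=None)
    fitted = xab @ coef
    resid = y - fitted
    y_fl = fitted[:, None] + resid[idx]
    f_perm_inter = _seq_f(qs, dfs, df_res, y_fl)[2]

    results = []
    for name, f0, fp in (
        (factor_names[0], f_obs[0], f_perm_main[0]),
        (factor_names[1], f_obs[1], f_perm_main[1]),
        ("interaction", f_obs[2], f_perm_inter),
    ):
        results.append(
            PermTestResult(
                response=response,
                occasion=occasion,
                factor=name,
                f_obs=f0,
                p_perm=_p_value(fp, f0, exhaustive),
                n_perm=n_done,
                exhaustive=exhaustive,
                seed=seed,
            )
        )
    return results


def within_group_perm_test(
    y,
    treatment,
    n_perm: int = 4999,
    seed: int | None = None,
    response: str = "y",
    occasion: str = "",
    factor: str = "treatment",
) -> PermTestResult:
    """Two-sided two-sample permutation test on the difference of means."""
    y = np.asarray(y, dtype=float)
    codes, levels = _codes(treatment)
    if len(levels) != 2:
        raise ValueError(f"within-group test needs exactly 2 treatment levels, got {len(levels)}")
    n = y.size
    n1 = int(np.count_nonzero(codes == 1))
    n0 = n - n1
    d_obs = float(y[codes == 1].mean() - y[codes == 0].mean())

    total = math.comb(n, n1)
    s_all = float(y.sum())
    if total <= n_perm:
        sums1 = np.array(
            [y[list(c)].sum() for c in itertools.combinations(range(n), n1)]
        )
        d_perm = sums1 / n1 - (s_all - sums1) / n0
        p = _p_value(np.abs(d_perm), abs(d_obs), exhaustive=True)
        n_done, exhaustive = total, True
    else:
        rng = np.random.default_rng(seed)
        idx, _ = _perm_indices(rng, n, n_perm)
        mask = (codes == 1).astype(float)
        sums1 = mask @ y[idx]
        d_perm = sums1 / n1 - (s_all - sums1) / n0
        p = _p_value(np.abs(d_perm), abs(d_obs), exhaustive=False)
        n_done, exhaustive = n_perm, False

    # equivalent one-way F for reporting
    ssb = d_obs**2 * n1 * n0 / n
    sst = float(np.sum((y - y.mean()) ** 2))
    ssw = sst - ssb
    f_obs = float(ssb / (ssw / (n - 2))) if ssw > 0 else (0.0 if ssb == 0 else float("inf"))
    return PermTestResult(
        response=response,
        occasion=occasion,
        factor=factor,
        f_obs=f_obs,
        p_perm=p,
        n_perm=n_done,
        exhaustive=exhaustive,
        seed=seed,
    )


def _codes(labels) -> tuple[np.ndarray, list]:
    labels = np.asarray(labels)
    levels, codes = np.unique(labels, return_inverse=True)
    return codes.astype(np.intp), list(levels)
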