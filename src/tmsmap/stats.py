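"""Two-way repeated-measures ANOVA with sphericity handling.

Implements the group-level inference chain used for motor-map metrics:
a fully within-subject two-way ANOVA (each effect tested against its
subject-interaction error term), Mauchly's sphericity test on the
orthonormal-contrast covariance, Greenhouse-Geisser (GG)
degrees-of-freedom correction applied whenever Mauchly rejects at the
configured threshold, and Bonferroni-corrected pairwise paired-t
post-hocs.

The decomposition is computed directly on the balanced (n, a, b) cell
array, which keeps a single call cheap enough for Monte-Carlo
calibration at thousands of replicates.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "rm_anova_2way",
    "rm_anova_cells",
    "mauchly_sphericity",
    "gg_correction",
    "bonferroni_posthoc",
    "BalanceError",
]


class BalanceError(ValueError):
    """The design is not fully balanced (some subject x cell is missing)."""


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1, k) orthonormal rows spanning the complement of the unit vector."""
    if k < 2:
        raise ValueError("need at least 2 levels")
    # Helmert contrasts, then QR-orthonormalised
    c = np.zeros((k - 1, k))
    for i in range(k - 1):
        c[i, : i + 1] = 1.0
        c[i, i + 1] = -(i + 1)
    q, _ = np.linalg.qr(c.T)
    return q.T


def _contrast_cov(scores: np.ndarray) -> np.ndarray:
    """Sample covariance (n-1 denominator) of per-subject contrast scores."""
    return np.cov(scores, rowvar=False, ddof=1).reshape(
        scores.shape[1], scores.shape[1]
    )


def _mauchly_from_cov(S: np.ndarray, n: int) -> tuple[float, float]:
    k = S.shape[0]
    if k == 1:
        return 1.0, 1.0
    det = np.linalg.det(S)
    tr = np.trace(S)
    if det <= 0 or tr <= 0:
        # singular contrast covariance (n too small for the effect)
        return 0.0, 0.0
    W = float(det / (tr / k) ** k)
    W = min(W, 1.0)
    d = 1.0 - (2.0 * k**2 + k + 2.0) / (6.0 * k * (n - 1.0))
    chi2 = -(n - 1.0) * d * np.log(W)
    df = k * (k + 1) / 2.0 - 1.0
    return W, float(sps.chi2.sf(chi2, df))


def _gg_epsilon_from_cov(S: np.ndarray) -> float:
    k = S.shape[0]
    if k == 1:
        return 1.0
    lam = np.linalg.eigvalsh(S)
    lam = np.clip(lam, 0.0, None)
    denom = k * np.sum(lam**2)
    if denom <= 0:
        return 1.0
    eps = float(np.sum(lam) ** 2 / denom)
    return float(np.clip(eps, 1.0 / k, 1.0))


def _effect_scores(Y: np.ndarray, effect: str) -> np.ndarray:
    """Per-subject orthonormal-contrast scores for an effect of a (n,a,b) array."""
    n, a, b = Y.shape
    if effect == "A":
        return Y.mean(axis=2) @ _orthonormal_contrasts(a).T
    if effect == "B":
        return Y.mean(axis=1) @ _orthonormal_contrasts(b).T
    if effect == "AxB":
        M = np.kron(_orthonormal_contrasts(a), _orthonormal_contrasts(b))
        return Y.reshape(n, a * b) @ M.T
    raise ValueError(f"unknown effect {effect!r}")


def rm_anova_cells(
    Y: np.ndarray,
    factor_names: tuple[str, str] = ("A", "B"),
    gg_alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-way within-subject ANOVA on a balanced (n, a, b) cell array.

    Returns one row per effect (A, B, A x B; single-level factors are
    dropped) with columns ``F, df1, df2, p_uncorrected, sphericity_W,
    sphericity_p, gg_epsilon, df1_gg, df2_gg, p_gg, gg_applied, p``.
    ``gg_applied`` is True when Mauchly rejects at ``gg_alpha`` (or when
    the contrast covariance is singular, where the uncorrected test is
    not trustworthy either); ``p`` is then the GG-corrected p-value.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 3:
        raise ValueError("Y must be (n_subjects, a_levels, b_levels)")
    n, a, b = Y.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    gm = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_sa = Y.mean(axis=2)
    m_sb = Y.mean(axis=1)
    m_ab = Y.mean(axis=0)

    rows = []
    # sums of squares at float-rounding level (relative to the total) are
    # treated as exactly zero so constant-effect data yields F = 0, not 0/0
    ss_floor = 1e-12 * max(float(np.sum((Y - gm) ** 2)), np.finfo(float).tiny)

    def add_effect(name, effect_key, ss_eff, df_eff, ss_err, df_err, n_levels):
        ss_eff = 0.0 if ss_eff < ss_floor else ss_eff
        ss_err = 0.0 if ss_err < ss_floor else ss_err
        ms_err = ss_err / df_err
        if ms_err > 0:
            F = (ss_eff / df_eff) / ms_err
        else:
            F = 0.0 if ss_eff == 0.0 else float("inf")
        p_unc = float(sps.f.sf(F, df_eff, df_err))
        if n_levels > 2:
            S = _contrast_cov(_effect_scores(Y, effect_key))
            W, p_W = _mauchly_from_cov(S, n)
            eps = _gg_epsilon_from_cov(S)
            singular = W == 0.0 and p_W == 0.0
            applied = bool(p_W < gg_alpha) or singular
            if singular:
                W, p_W = float("nan"), float("nan")
        else:
            W, p_W, eps, applied = 1.0, 1.0, 1.0, False
        p_gg = float(sps.f.sf(F, eps * df_eff, eps * df_err))
        rows.append(
            {
                "effect": name,
                "F": float(F),
                "df1": df_eff,
                "df2": df_err,
                "p_uncorrected": p_unc,
                "sphericity_W": W,
                "sphericity_p": p_W,
                "gg_epsilon": eps,
                "df1_gg": eps * df_eff,
                "df2_gg": eps * df_err,
                "p_gg": p_gg,
                "gg_applied": applied,
                "p": p_gg if applied else p_unc,
            }
        )

    if a > 1:
        ss_a = n * b * np.sum((m_a - gm) ** 2)
        ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + gm) ** 2)
        add_effect(factor_names[0], "A", ss_a, a - 1, ss_as, (a - 1) * (n - 1), a)
    if b > 1:
        ss_b = n * a * np.sum((m_b - gm) ** 2)
        ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + gm) ** 2)
        add_effect(factor_names[1], "B", ss_b, b - 1, ss_bs, (b - 1) * (n - 1), b)
    if a > 1 and b > 1:
        resid_ab = m_ab - m_a[:, None] - m_b[None, :] + gm
        ss_ab = n * np.sum(resid_ab**2)
        resid_full = (
            Y
            - m_sa[:, :, None]
            - m_sb[:, None, :]
            - m_ab[None, :, :]
            + m_s[:, None, None]
            + m_a[None, :, None]
            + m_b[None, None, :]
            - gm
        )
        ss_abs = np.sum(resid_full**2)
        add_effect(
            f"{factor_names[0]} x {factor_names[1]}",
            "AxB",
            ss_ab,
            (a - 1) * (b - 1),
            ss_abs,
            (a - 1) * (b - 1) * (n - 1),
            (a - 1) * (b - 1) + 1,
        )
    return pd.DataFrame(rows).set_index("effect")


def _to_cells(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    factors: tuple[str, str],
) -> tuple[np.ndarray, list, list, list]:
    fa, fb = factors
    counts = data.groupby([subject, fa, fb], observed=True)[dv].count()
    subjects = sorted(data[subject].unique())
    la = sorted(data[fa].unique())
    lb = sorted(data[fb].unique())
    full = pd.MultiIndex.from_product([subjects, la, lb], names=[subject, fa, fb])
    missing = full.difference(counts.index)
    if len(missing):
        raise BalanceError(f"missing cells: {list(missing[:10])}")
    if (counts > 1).any():
        # replicated cells are averaged within subject x condition upstream
        data = data.groupby([subject, fa, fb], observed=True, as_index=False)[dv].mean()
    wide = data.set_index([subject, fa, fb])[dv].unstack([fa, fb])
    Y = (
        wide.reindex(index=subjects)
        .reindex(columns=pd.MultiIndex.from_product([la, lb]))
        .to_numpy()
        .reshape(len(subjects), len(la), len(lb))
    )
    return Y, subjects, la, lb


def rm_anova_2way(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    factors: tuple[str, str] = ("A", "B"),
    gg_alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-way repeated-measures ANOVA from a long-format table.

    ``data`` must be fully balanced (every subject x cell present;
    replicated cells are averaged within subject and condition). See
    :func:`rm_anova_cells` for the returned columns.
    """
    Y, _, _, _ = _to_cells(data, dv, subject, factors)
    return rm_anova_cells(Y, factors, gg_alpha=gg_alpha)


def _scores_from_table(
    data: pd.DataFrame, dv: str, subject: str, factors: tuple[str, str], effect: str
) -> tuple[np.ndarray, int, int]:
    Y, subjects, la, lb = _to_cells(data, dv, subject, factors)
    if effect == factors[0]:
        key, k = "A", len(la)
    elif effect == factors[1]:
        key, k = "B", len(lb)
    else:
        raise ValueError(f"effect must be one of {factors}")
    return _effect_scores(Y, key), len(subjects), k


def mauchly_sphericity(
    data: pd.DataFrame,
    effect: str,
    dv: str = "value",
    subject: str = "subject",
    factors: tuple[str, str] = ("A", "B"),
) -> tuple[float, float]:
    """Mauchly's W and chi-square p-value for one within factor.

    With two levels sphericity holds automatically (W = 1, p = 1). A
    singular contrast covariance (too few subjects for the number of
    levels) raises.
    """
    scores, n, k = _scores_from_table(data, dv, subject, factors, effect)
    if k == 2:
        return 1.0, 1.0
    S = _contrast_cov(scores)
    W, p = _mauchly_from_cov(S, n)
    if W == 0.0 and p == 0.0:
        raise ValueError(
            f"contrast covariance for effect {effect!r} is singular "
            f"(n = {n} too small for {k} levels)"
        )
    return W, p


def gg_correction(
    data: pd.DataFrame,
    effect: str,
    dv: str = "value",
    subject: str = "subject",
    factors: tuple[str, str] = ("A", "B"),
) -> float:
    """Greenhouse-Geisser epsilon for one within factor (1 for 2 levels)."""
    scores, _, k = _scores_from_table(data, dv, subject, factors, effect)
    if k == 2:
        return 1.0
    return _gg_epsilon_from_cov(_contrast_cov(scores))


def bonferroni_posthoc(
    data: pd.DataFrame,
    effect: str,
    dv: str = "value",
    subject: str = "subject",
    factors: tuple[str, str] | tuple[str] = ("A", "B"),
) -> pd.DataFrame:
    """All pairwise paired-t comparisons between levels of one factor.

    The other factor (if any) is averaged out within subject first. The
    family is the k(k-1)/2 comparisons within this effect;
    ``p_adj = min(1, m * p_raw)``.
    """
    others = [f for f in factors if f != effect]
    if effect not in factors:
        raise ValueError(f"effect must be one of {factors}")
    collapsed = data.groupby([subject, effect], observed=True, as_index=False)[dv].mean()
    wide = collapsed.pivot(index=subject, columns=effect, values=dv)
    if wide.isna().any().any():
        raise BalanceError("missing subject x level cells")
    levels = list(wide.columns)
    pairs = list(itertools.combinations(levels, 2))
    m = len(pairs)
    rows = []
    for la, lb in pairs:
        t, p = sps.ttest_rel(wide[la], wide[lb])
        rows.append(
            {
                "level_a": la,
                "level_b": lb,
                "mean_diff": float((wide[la] - wide[lb]).mean()),
                "t": float(t),
                "p_raw": float(p),
                "p_adj": float(min(1.0, m * p)),
                "n_comparisons": m,
            }
        )
    return pd.DataFrame(rows)
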