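"""Two-way repeated-measures ANOVA on channel-averaged peak values.

The design is 3 (task) × 2 (familiarity), fully within subjects, with one
value per participant × cell (trial-level peak values pre-averaged).  For
each effect the table reports the sum of squares, its subject-interaction
error term, F, the Greenhouse–Geisser ε with the corrected p, and the
generalized eta squared η²G for fully-within designs:

    η²G = SS_effect / (SS_effect + SS_subjects + Σ all error SS).

Greenhouse–Geisser ε is estimated from the covariance S of the cell scores
through the effect's orthonormal contrast C:

    ε̂ = tr(C S Cᵀ)² / (d · tr((C S Cᵀ)²)),   clipped to [1/d, 1],

which is exactly 1 for a two-level factor.  Both the uncorrected and the
corrected p are reported; significance calls use the corrected one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

TASK_ORDER = ("visual-active", "auditory-active", "control")
FAM_ORDER = ("familiar", "unfamiliar")
EFFECTS = ("task", "familiarity", "task:familiarity")


class DegenerateDesignError(ValueError):
    pass


def build_design(peak_table: pd.DataFrame, value: str = "pos_value"):
    """Average trial-level peak values to one number per participant ×
    task × familiarity cell; participants missing any of the 6 cells are
    dropped (listwise).  Returns (design DataFrame, exclusion log)."""
    df = peak_table.copy()
    cells = (df.groupby(["participant", "task", "familiarity"], sort=False)[value]
             .mean().reset_index().rename(columns={value: "value"}))
    full = [(t, f) for t in TASK_ORDER for f in FAM_ORDER]
    dropped = []
    keep = []
    for p, sub in cells.groupby("participant", sort=False):
        have = set(zip(sub["task"], sub["familiarity"]))
        missing = [c for c in full if c not in have]
        if missing:
            dropped.append({"participant": p, "missing_cells": missing})
        else:
            keep.append(sub)
    if not keep:
        raise DegenerateDesignError("no participant has all 6 cells")
    design = pd.concat(keep, ignore_index=True)
    return design, dropped


def _orthonormal_contrast(k: int) -> np.ndarray:
    return linalg.helmert(k, full=False)      # (k-1) × k, rows orthonormal, sum 0


def gg_epsilon(level_scores, contrast: np.ndarray | None = None) -> float:
    """Greenhouse–Geisser ε̂ from a participant × level score matrix."""
    M = np.asarray(level_scores, dtype=float)
    n, k = M.shape
    if k < 2:
        raise DegenerateDesignError("need at least 2 levels")
    if n < 2:
        raise DegenerateDesignError("need at least 2 participants for a covariance")
    C = _orthonormal_contrast(k) if contrast is None else np.asarray(contrast)
    d = C.shape[0]
    S = np.cov(M, rowvar=False)
    G = C @ np.atleast_2d(S) @ C.T
    tr = np.trace(G)
    tr2 = np.trace(G @ G)
    if tr2 <= 0:
        return 1.0
    return float(np.clip(tr ** 2 / (d * tr2), 1.0 / d, 1.0))


@dataclass
class RMAnovaResults:
    """Fitted two-way RM-ANOVA: effect table plus the SS decomposition."""

    table: pd.DataFrame
    ss_subjects: float
    ss_total: float
    n_participants: int
    cell_means: pd.DataFrame

    def summary(self) -> str:
        lines = [f"Two-way repeated-measures ANOVA  (n = {self.n_participants} participants)",
                 f"{'effect':<18}{'df':>12}{'F':>10}{'eps':>7}{'p(GG)':>10}{'eta_g^2':>9}"]
        for _, r in self.table.iterrows():
            df_str = f"({r.df1 * r.gg_epsilon:.2f}, {r.df2 * r.gg_epsilon:.2f})"
            lines.append(f"{r.effect:<18}{df_str:>12}{r.F:>10.4f}{r.gg_epsilon:>7.3f}"
                         f"{r.p_gg:>10.4f}{r.eta_g_squared:>9.4f}")
        return "\n".join(lines)

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]


class RMAnova:
    """3 (task) × 2 (familiarity) fully-within ANOVA model.

    Parameters
    ----------
    design : DataFrame
        Columns participant, task, familiarity, value; one row per cell,
        every participant complete.
    """

    def __init__(self, design: pd.DataFrame):
        self.design = design

    def fit(self) -> RMAnovaResults:
        df = self.design
        parts = list(dict.fromkeys(df["participant"]))
        a, b = len(TASK_ORDER), len(FAM_ORDER)
        n = len(parts)
        if n < 2:
            raise DegenerateDesignError("need at least 2 complete participants")
        Y = np.full((n, a, b), np.nan)
        for _, r in df.iterrows():
            Y[parts.index(r["participant"]),
              TASK_ORDER.index(r["task"]), FAM_ORDER.index(r["familiarity"])] = r["value"]
        if np.isnan(Y).any():
            raise DegenerateDesignError("design is not fully crossed")

        g = Y.mean()
        if np.allclose(Y, g):
            raise DegenerateDesignError("zero total variance")
        m_i = Y.mean(axis=(1, 2))
        m_a = Y.mean(axis=(0, 2))
        m_b = Y.mean(axis=(0, 1))
        m_ia = Y.mean(axis=2)
        m_ib = Y.mean(axis=1)
        m_ab = Y.mean(axis=0)

        ss_s = a * b * np.sum((m_i - g) ** 2)
        ss_a = n * b * np.sum((m_a - g) ** 2)
        ss_b = n * a * np.sum((m_b - g) ** 2)
        ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + g) ** 2)
        ss_as = b * np.sum((m_ia - m_i[:, None] - m_a[None, :] + g) ** 2)
        ss_bs = a * np.sum((m_ib - m_i[:, None] - m_b[None, :] + g) ** 2)
        ss_total = np.sum((Y - g) ** 2)
        ss_abs = ss_total - (ss_s + ss_a + ss_b + ss_ab + ss_as + ss_bs)

        cells = Y.reshape(n, a * b)          # column order: (task, familiarity)
        C_a = np.kron(_orthonormal_contrast(a), np.ones((1, b)) / np.sqrt(b))
        C_b = np.kron(np.ones((1, a)) / np.sqrt(a), _orthonormal_contrast(b))
        C_ab = np.kron(_orthonormal_contrast(a), _orthonormal_contrast(b))

        err_sum = ss_as + ss_bs + ss_abs
        rows = []
        for name, ss, err, df1, C in (
                ("task", ss_a, ss_as, a - 1, C_a),
                ("familiarity", ss_b, ss_bs, b - 1, C_b),
                ("task:familiarity", ss_ab, ss_abs, (a - 1) * (b - 1), C_ab)):
            df2 = df1 * (n - 1)
            F = (ss / df1) / (err / df2) if err > 0 else np.inf
            eps = gg_epsilon(cells, contrast=C)
            rows.append({
                "effect": name, "ss_effect": ss, "ss_error": err,
                "df1": df1, "df2": df2, "F": F,
                "gg_epsilon": eps,
                "p_uncorrected": float(stats.f.sf(F, df1, df2)),
                "p_gg": float(stats.f.sf(F, df1 * eps, df2 * eps)),
                "eta_g_squared": ss / (ss + ss_s + err_sum)})
        table = pd.DataFrame(rows)
        means = pd.DataFrame(m_ab, index=list(TASK_ORDER), columns=list(FAM_ORDER))
        return RMAnovaResults(table=table, ss_subjects=float(ss_s),
                              ss_total=float(ss_total), n_participants=n,
                              cell_means=means)


def rm_anova_2way(design: pd.DataFrame) -> RMAnovaResults:
    return RMAnova(design).fit()


def _null_design(rng, n_participants, subject_sd=1.0, noise_sd=1.0,
                 familiarity_shift=0.0):
    rows = []
    for i in range(n_participants):
        s = subject_sd * rng.standard_normal()
        for t in TASK_ORDER:
            for f in FAM_ORDER:
                shift = familiarity_shift if f == "unfamiliar" else 0.0
                rows.append({"participant": f"p{i}", "task": t, "familiarity": f,
                             "value": s + shift + noise_sd * rng.standard_normal()})
    return pd.DataFrame(rows)


def type1_check(n_sims: int = 1000, seed: int = 0, n_participants: int = 14,
                alpha: float = 0.05, familiarity_shift: float = 0.0) -> dict:
    """Fraction of simulated designs with p_gg < alpha, per effect.

    With ``familiarity_shift=0`` (exchangeable participant noise, no effects)
    this is the empirical type-I error rate; a nonzero shift turns it into a
    power simulation for the familiarity effect.
    """
    if n_sims < 100:
        raise ValueError("need at least 100 simulations")
    rng = np.random.default_rng(seed)
    hits = {e: 0 for e in EFFECTS}
    for _ in range(n_sims):
        res = rm_anova_2way(_null_design(rng, n_participants,
                                         familiarity_shift=familiarity_shift))
        for e in EFFECTS:
            if res.effect(e)["p_gg"] < alpha:
                hits[e] += 1
    return {e: hits[e] / n_sims for e in EFFECTS}
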