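"""Group- and treatment-level statistics on betweenness hub profiles.

The inferential procedure, per frequency band:

1. A mixed (split-plot) repeated-measures ANOVA on the subject x electrode
   betweenness table — group (control vs patient) as the between-subject
   factor, electrode (16 nodes) as the within-subject factor.  Within
   effects are tested with Greenhouse-Geisser corrected degrees of
   freedom (epsilon from the pooled within-group covariance of the node
   values); the between effect is uncorrected, per standard split-plot
   practice.  Effect sizes are partial eta-squared.
2. Bands whose group main effect or group x node interaction reaches
   P < 0.05 (GG-corrected where applicable) are gated through to post hoc
   per-electrode t-tests, with Benjamini-Hochberg FDR control across the
   16 electrodes of that band at q < 0.05.  Interaction p-values are
   additionally BH-corrected across the five bands and reported in their
   own column (two distinct correction scopes, never conflated).
3. For treatment studies, a two-way within-subject ANOVA (treatment x
   node) with paired post hoc t-tests under the same gating and FDR
   rules.
4. Pearson correlations of hub betweenness against clinical score and
   age, and a paired t-test on the clinical score itself.

Sums of squares use the weighted (Type II) decomposition, which is exact
for this design and agrees with common repeated-measures software for
unbalanced group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


class GatingError(RuntimeError):
    """Raised when post hoc tests are requested for an ungated band."""


@dataclass
class AnovaResult:
    band: str
    effect: str  # group | node | group x node | treatment | treatment x node
    F: float
    df1: float
    df2: float
    ss_effect: float
    ss_error: float
    epsilon: float  # 1.0 where no correction applies (between effects)
    p_unc: float
    p_gg: float
    eta_sq: float  # partial eta-squared
    p_fdr_bands: Optional[float] = None  # BH across bands (interaction only)

    @property
    def significant(self) -> bool:
        return self.p_gg < 0.05


@dataclass
class PosthocResult:
    band: str
    electrode: str
    t: float
    df: float
    p_raw: float
    q_bh: float
    direction: int  # sign of (patient - control) or (post - pre)

    @property
    def significant(self) -> bool:
        return self.q_bh < 0.05


@dataclass
class CorrelationResult:
    pair: str
    r: float
    p: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p < 0.05


# ---------------------------------------------------------------------------
# Greenhouse-Geisser epsilon
# ---------------------------------------------------------------------------

def gg_epsilon(within_covariance: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon-hat of a k x k within-subject covariance.

    With A the double-centered covariance, eps = tr(A)^2 / ((k-1) sum A^2),
    clipped to [1/(k-1), 1].  Equals 1 exactly under compound symmetry.
    """
    S = np.asarray(within_covariance, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(S, S.T, rtol=1e-8, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    k = S.shape[0]
    if k < 2:
        raise ValueError("need at least 2 within-subject levels")
    H = np.eye(k) - np.ones((k, k)) / k
    A = H @ S @ H
    denom = (k - 1) * float(np.sum(A * A))
    if denom == 0:
        return 1.0
    eps = float(np.trace(A)) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def _pooled_within_cov(values: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Pooled within-group covariance of the node columns."""
    S = np.zeros((values.shape[1], values.shape[1]))
    dof = 0
    for g in np.unique(groups):
        sub = values[groups == g]
        if len(sub) > 1:
            S += (len(sub) - 1) * np.cov(sub, rowvar=False)
            dof += len(sub) - 1
    if dof == 0:
        raise ValueError("no within-group degrees of freedom for covariance")
    return S / dof


def _f_result(band, effect, ss_eff, df1, ss_err, df2, eps,
              ss_scale: float = 0.0) -> AnovaResult:
    # scrub floating-point residue so degenerate designs read as exact zeros
    tiny = 1e-12 * max(ss_scale, 1e-300)
    if abs(ss_eff) <= tiny:
        ss_eff = 0.0
    if ss_err <= tiny:
        ss_err = 0.0
    ms_eff = ss_eff / df1
    ms_err = ss_err / df2
    if ms_err == 0:
        if np.isclose(ss_eff, 0.0):  # no effect, no error: F := 0
            ms_eff, F = 0.0, 0.0
        else:
            raise ValueError(
                f"zero error variance for effect {effect!r}: degenerate input"
            )
    else:
        F = ms_eff / ms_err
    p_unc = float(stats.f.sf(F, df1, df2))
    p_gg = float(stats.f.sf(F, df1 * eps, df2 * eps))
    eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
    return AnovaResult(band=band, effect=effect, F=float(F), df1=df1, df2=df2,
                       ss_effect=float(ss_eff), ss_error=float(ss_err),
                       epsilon=float(eps), p_unc=p_unc, p_gg=p_gg,
                       eta_sq=float(eta))


# ---------------------------------------------------------------------------
# Mixed (split-plot) ANOVA: group between, node within
# ---------------------------------------------------------------------------

def rm_anova_mixed(
    bc_table: np.ndarray, groups: Sequence[str], band: str = ""
) -> list[AnovaResult]:
    """Split-plot ANOVA of a subjects x nodes table with a 2-level group factor.

    Returns results for the group main effect (uncorrected df), the node
    main effect and the group x node interaction (both GG-corrected, with
    epsilon from the pooled within-group node covariance).
    """
    x = np.asarray(bc_table, dtype=float)
    groups = np.asarray(groups)
    if x.ndim != 2:
        raise ValueError("bc_table must be subjects x nodes")
    if np.any(~np.isfinite(x)):
        raise ValueError("bc_table contains missing cells")
    if len(groups) != x.shape[0]:
        raise ValueError("group labels do not match subject count")
    levels = np.unique(groups)
    n_g = np.array([(groups == g).sum() for g in levels])
    if len(levels) < 2 or np.any(n_g < 2):
        raise ValueError("need at least 2 subjects in each of >= 2 groups")
    N, k = x.shape
    G = len(levels)

    grand = x.mean()
    ss_total = float(((x - grand) ** 2).sum())
    m_subj = x.mean(axis=1)
    m_node = x.mean(axis=0)
    m_group = np.array([x[groups == g].mean() for g in levels])
    cell = np.stack([x[groups == g].mean(axis=0) for g in levels])  # G x k

    ss_group = float(k * (n_g * (m_group - grand) ** 2).sum())
    ss_resbetw = float(
        k * sum(((m_subj[groups == g] - m_group[i]) ** 2).sum()
                for i, g in enumerate(levels))
    )
    ss_node = float(N * ((m_node - grand) ** 2).sum())
    ss_resall = float(
        sum(((x[groups == g] - cell[i]) ** 2).sum() for i, g in enumerate(levels))
    )
    ss_inter = ss_total - ss_resall - ss_node - ss_group
    ss_reswith = ss_resall - ss_resbetw

    eps = gg_epsilon(_pooled_within_cov(x, groups))
    df_err_b = N - G
    df_err_w = (N - G) * (k - 1)
    return [
        _f_result(band, "group", ss_group, G - 1, ss_resbetw, df_err_b, 1.0,
                  ss_scale=ss_total),
        _f_result(band, "node", ss_node, k - 1, ss_reswith, df_err_w, eps,
                  ss_scale=ss_total),
        _f_result(band, "group x node", ss_inter, (G - 1) * (k - 1),
                  ss_reswith, df_err_w, eps, ss_scale=ss_total),
    ]


# ---------------------------------------------------------------------------
# Two-way within ANOVA: treatment x node, both within-subject
# ---------------------------------------------------------------------------

def rm_anova_prepost(
    bc_pre: np.ndarray, bc_post: np.ndarray, band: str = ""
) -> list[AnovaResult]:
    """Two-way fully-within ANOVA on paired session tables (subjects x nodes).

    Each effect is tested against its interaction with subjects.  The
    treatment factor has two levels, so its epsilon is exactly 1; the node
    and treatment x node epsilons come from the covariance of the session
    means and of the session differences respectively.
    """
    pre = np.asarray(bc_pre, dtype=float)
    post = np.asarray(bc_post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 2:
        raise ValueError("pre and post tables must be equal-shape subjects x nodes")
    if np.any(~np.isfinite(pre)) or np.any(~np.isfinite(post)):
        raise ValueError("session tables contain missing cells")
    n, k = pre.shape
    if n < 2:
        raise ValueError("need at least 2 paired subjects")
    x = np.stack([pre, post], axis=1)  # subject x session x node
    A = 2

    grand = x.mean()
    m_s = x.mean(axis=(1, 2))
    m_a = x.mean(axis=(0, 2))
    m_j = x.mean(axis=(0, 1))
    m_sa = x.mean(axis=2)
    m_sj = x.mean(axis=1)
    m_aj = x.mean(axis=0)

    ss_total = float(((x - grand) ** 2).sum())
    ss_subj = float(A * k * ((m_s - grand) ** 2).sum())
    ss_treat = float(n * k * ((m_a - grand) ** 2).sum())
    ss_node = float(n * A * ((m_j - grand) ** 2).sum())
    ss_sa = float(k * ((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum())
    ss_sj = float(A * ((m_sj - m_s[:, None] - m_j[None, :] + grand) ** 2).sum())
    ss_aj = float(n * ((m_aj - m_a[:, None] - m_j[None, :] + grand) ** 2).sum())
    ss_saj = ss_total - ss_subj - ss_treat - ss_node - ss_sa - ss_sj - ss_aj

    eps_node = gg_epsilon(np.cov(m_sj, rowvar=False))
    eps_inter = gg_epsilon(np.cov(post - pre, rowvar=False))
    return [
        _f_result(band, "treatment", ss_treat, A - 1, ss_sa, n - 1, 1.0,
                  ss_scale=ss_total),
        _f_result(band, "node", ss_node, k - 1, ss_sj, (n - 1) * (k - 1),
                  eps_node, ss_scale=ss_total),
        _f_result(band, "treatment x node", ss_aj, (A - 1) * (k - 1),
                  ss_saj, (n - 1) * (A - 1) * (k - 1), eps_inter,
                  ss_scale=ss_total),
    ]


# ---------------------------------------------------------------------------
# BH-FDR and post hoc t-tests
# ---------------------------------------------------------------------------

def bh_fdr(p_values: Sequence[float], q_threshold: float = 0.05
           ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted q-values and the rejection mask."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=q_threshold, method="fdr_bh")
    return q, reject


def _check_gate(anova: Sequence[AnovaResult], band: str, alpha: float) -> None:
    relevant = [a for a in anova if a.band == band and
                a.effect in ("group", "group x node", "treatment", "treatment x node")]
    if not relevant:
        raise GatingError(f"no ANOVA results supplied for band {band!r}")
    if not any(a.p_gg < alpha for a in relevant):
        raise GatingError(
            f"band {band!r} has no significant main or interaction effect; "
            "post hoc tests are not licensed"
        )


def posthoc_ttests(
    bc_table: np.ndarray,
    band: str,
    electrodes: Sequence[str],
    anova: Sequence[AnovaResult],
    groups: Optional[Sequence[str]] = None,
    paired_post: Optional[np.ndarray] = None,
    alpha: float = 0.05,
    q_threshold: float = 0.05,
    control_label: str = "control",
) -> list[PosthocResult]:
    """Per-electrode post hoc t-tests for a gated band, BH-FDR across electrodes.

    Group contrast (``groups`` given): independent two-sample t per
    electrode, direction = sign(patient - control).  Treatment contrast
    (``paired_post`` given): paired t per electrode on (post - pre),
    direction = sign(post - pre).  Raises :class:`GatingError` when the
    band's ANOVA shows no significant effect at *alpha*.
    """
    if (groups is None) == (paired_post is None):
        raise ValueError("supply exactly one of groups or paired_post")
    _check_gate(anova, band, alpha)
    x = np.asarray(bc_table, dtype=float)
    k = x.shape[1]
    if len(electrodes) != k:
        raise ValueError("electrode labels do not match table width")

    ts, dfs, ps, dirs = [], [], [], []
    if groups is not None:
        groups = np.asarray(groups)
        labels = np.unique(groups)
        other = [g for g in labels if g != control_label]
        if control_label not in labels or len(other) != 1:
            raise ValueError("group contrast needs control plus one other group")
        a = x[groups == other[0]]  # patient
        b = x[groups == control_label]
        for j in range(k):
            if np.var(a[:, j]) == 0 and np.var(b[:, j]) == 0:
                diff = a[:, j].mean() - b[:, j].mean()
                # degenerate: no within-group variability at this electrode
                t = float(np.sign(diff) * np.inf) if diff != 0 else 0.0
                p = 0.0 if diff != 0 else 1.0
                df = len(a) + len(b) - 2
            else:
                res = stats.ttest_ind(a[:, j], b[:, j], equal_var=True)
                t, p, df = float(res.statistic), float(res.pvalue), len(a) + len(b) - 2
            ts.append(t); dfs.append(df); ps.append(p)
            dirs.append(int(np.sign(a[:, j].mean() - b[:, j].mean())))
    else:
        post = np.asarray(paired_post, dtype=float)
        if post.shape != x.shape:
            raise ValueError("paired sessions must have identical shape")
        d = post - x
        for j in range(k):
            if np.var(d[:, j]) == 0:
                # constant difference: same convention as paired_ttest
                m = d[:, j].mean()
                t = float(np.sign(m) * np.inf) if m != 0 else 0.0
                p = 0.0 if m != 0 else 1.0
            else:
                res = stats.ttest_rel(post[:, j], x[:, j])
                t, p = float(res.statistic), float(res.pvalue)
            ts.append(t); dfs.append(x.shape[0] - 1); ps.append(p)
            dirs.append(int(np.sign(d[:, j].mean())))

    qs, _ = bh_fdr(ps, q_threshold)
    return [
        PosthocResult(band=band, electrode=electrodes[j], t=ts[j], df=dfs[j],
                      p_raw=ps[j], q_bh=float(qs[j]), direction=dirs[j])
        for j in range(k)
    ]


# ---------------------------------------------------------------------------
# Correlations, paired t, top edges
# ---------------------------------------------------------------------------

def pearson_corr(x: Sequence[float], y: Sequence[float], pair: str = ""
                 ) -> CorrelationResult:
    """Pearson r with two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need equal-length 1-D vectors with n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(pair=pair, r=float(res.statistic),
                             p=float(res.pvalue), n=x.size)


def paired_ttest(pre: Sequence[float], post: Sequence[float]
                 ) -> tuple[float, int, float]:
    """Classic paired t-test; returns (t, df, two-sided p).

    A zero-variance, nonzero mean difference yields t = +/-inf, p = 0."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("paired vectors must have equal length")
    n = pre.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = post - pre
    if np.var(d) == 0:
        if d.mean() == 0:
            return 0.0, n - 1, 1.0
        return float(np.sign(d.mean()) * np.inf), n - 1, 0.0
    res = stats.ttest_rel(post, pre)
    return float(res.statistic), n - 1, float(res.pvalue)


def top_edges(
    values: np.ndarray, labels: Sequence[str], fraction: float = 0.2
) -> list[tuple[str, str, float]]:
    """The strongest ceil(fraction * n(n-1)/2) unordered edges of a PLI matrix.

    Ties at the cut are broken by lexicographic electrode-pair order, so
    the selection is deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    v = np.asarray(values, dtype=float)
    n = v.shape[0]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sorted((str(labels[i]), str(labels[j])))
            edges.append((a, b, float(v[i, j])))
    edges.sort(key=lambda e: (-e[2], e[0], e[1]))
    m = int(np.ceil(fraction * n * (n - 1) / 2))
    return edges[:m]


def fdr_across_bands(anova: Sequence[AnovaResult],
                     effects: tuple[str, ...] = ("group x node", "treatment x node"),
                     q_threshold: float = 0.05) -> None:
    """Fill ``p_fdr_bands`` on interaction results: BH across the bands.

    This is the across-band correction scope, reported alongside (never in
    place of) the per-band GG-corrected p-values.
    """
    for effect in effects:
        rows = [a for a in anova if a.effect == effect]
        if not rows:
            continue
        qs, _ = bh_fdr([a.p_gg for a in rows], q_threshold)
        for a, q in zip(rows, qs):
            a.p_fdr_bands = float(q)
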