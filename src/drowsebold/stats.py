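"""Group statistics on state-conditioned band power (PSD at 0.05 Hz).

Three-step analysis stage operating on the long-format per-(participant,
ROI, state) band-power table:

1. a two-way ANOVA checking that time spent in the drowsiness states is
   concordant with participants' self-reported sleep (RSQ answers);
2. per-ROI generalized linear models of psd005 on state with a joint Wald
   test, Bonferroni-corrected across ROIs, followed by pairwise state
   comparisons with Cohen's d (pooled SD), Bonferroni-corrected across all
   emitted comparisons; plus pooled PERCLOS-psd005 linear regressions;
3. a network-level linear mixed model (random intercept per participant,
   state, network and their interaction as fixed factors) with per-network
   pairwise post-hoc comparisons.

Conventions: for the Gaussian family the joint state test uses the exact
F reference (so on balanced two-state data it coincides with the pooled
two-sample t-test); the reported Wald chi-square is F x df_num.  The
Gamma-log variant uses the asymptotic chi-square.  Participants missing a
state simply contribute no row for it (unbalanced data, no imputation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .states import STATE_NAMES

__all__ = [
    "bonferroni_alpha",
    "cohens_d",
    "RoiGlmResult",
    "roi_glm",
    "pairwise_posthoc",
    "perclos_psd_regression",
    "NetworkLmmResult",
    "network_lmm",
    "RsqAnovaResult",
    "rsq_anova",
]


def bonferroni_alpha(family_alpha: float = 0.05, m_tests: int = 1) -> float:
    """Per-test significance threshold after Bonferroni correction."""
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    return family_alpha / m_tests


def cohens_d(a, b) -> float:
    """Standardized mean difference (mean(a) - mean(b)) / pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("need at least two observations per group")
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        return 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


@dataclass
class RoiGlmResult:
    """Joint state test for one ROI."""

    roi: str
    wald_chi2: float
    df: int
    p_value: float
    family: str
    within_participant: bool
    n_obs: int
    significant: bool | None = None

    def summary(self) -> str:
        flag = "" if self.significant is None else f"  significant={self.significant}"
        return (f"ROI {self.roi}: Wald chi2({self.df}) = {self.wald_chi2:.2f}, "
                f"p = {self.p_value:.3g} [{self.family}"
                f"{', within-participant' if self.within_participant else ''}]"
                f"{flag}")


def _design(states: np.ndarray, participants: np.ndarray | None):
    """One-hot design [intercept | state dummies | participant dummies]."""
    s_levels = [s for s in STATE_NAMES if s in set(states)]
    n = states.size
    cols = [np.ones(n)]
    for s in s_levels[1:]:
        cols.append((states == s).astype(float))
    k_state = len(s_levels) - 1
    if participants is not None:
        p_levels = pd.unique(participants)
        for p in p_levels[1:]:
            cols.append((participants == p).astype(float))
    X = np.column_stack(cols)
    return X, k_state


def roi_glm(
    psd_table: pd.DataFrame,
    roi: str,
    family: str = "gaussian",
    within_participant: bool = False,
    value_col: str = "psd005",
) -> RoiGlmResult:
    """Joint test of a state effect on band power within one ROI.

    ``psd_table`` needs columns participant, roi, state and ``value_col``.
    ``family="gaussian"`` fits an identity-link linear model and tests the
    joint state contrast with an exact F (reported as Wald chi2 = F * df);
    ``family="gamma"`` fits a log-link Gamma GLM with an asymptotic Wald
    chi-square.  ``within_participant=True`` adds participant indicator
    covariates, exploiting the repeated-measures pairing of the design.
    """
    sub = psd_table.loc[psd_table["roi"] == roi]
    if sub.empty:
        raise ValueError(f"no rows for ROI {roi!r}")
    states = sub["state"].to_numpy()
    y = sub[value_col].to_numpy(dtype=float)
    n_states = len(set(states))
    if n_states < 2:
        raise ValueError(f"ROI {roi!r}: need >= 2 states, got {n_states}")
    if sub["participant"].nunique() < 2:
        raise ValueError(f"ROI {roi!r}: need >= 2 participants")
    if np.allclose(y.var(), 0):
        raise ValueError(f"ROI {roi!r}: zero-variance response")

    parts = sub["participant"].to_numpy() if within_participant else None
    X, k_state = _design(states, parts)
    X0 = np.delete(X, np.s_[1:1 + k_state], axis=1)  # drop state columns

    if family == "gaussian":
        rss1 = _rss(X, y)
        rss0 = _rss(X0, y)
        df2 = y.size - X.shape[1]
        if df2 < 1:
            raise ValueError("saturated design: no residual degrees of freedom")
        tiny = np.finfo(float).eps * y.size * y.var()
        if rss1 <= tiny:
            # perfect fit: state adds nothing if the reduced model fits too
            F = 0.0 if rss0 <= tiny else np.inf
        else:
            F = max(rss0 - rss1, 0.0) / k_state / (rss1 / df2)
        p = float(sps.f.sf(F, k_state, df2))
        chi2 = float(F * k_state)
    elif family == "gamma":
        import statsmodels.api as sm

        model = sm.GLM(y, X, family=sm.families.Gamma(sm.families.links.Log()))
        res = model.fit()
        L = np.zeros((k_state, X.shape[1]))
        L[np.arange(k_state), 1 + np.arange(k_state)] = 1.0
        w = res.wald_test(L, scalar=True)
        chi2 = float(w.statistic)
        p = float(w.pvalue)
    else:
        raise ValueError(f"unknown family {family!r}")
    return RoiGlmResult(roi=roi, wald_chi2=chi2, df=k_state, p_value=p,
                        family=family, within_participant=within_participant,
                        n_obs=int(y.size))


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def roi_glm_table(
    psd_table: pd.DataFrame,
    family_alpha: float = 0.05,
    **kwargs,
) -> pd.DataFrame:
    """Run :func:`roi_glm` for every ROI; Bonferroni across ROIs."""
    rois = list(pd.unique(psd_table["roi"]))
    thr = bonferroni_alpha(family_alpha, len(rois))
    rows = []
    for roi in rois:
        r = roi_glm(psd_table, roi, **kwargs)
        r.significant = r.p_value < thr
        rows.append(vars(r))
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_alpha"] = thr
    out.attrs["m_tests"] = len(rois)
    return out


def pairwise_posthoc(
    psd_table: pd.DataFrame,
    by: str = "roi",
    family_alpha: float = 0.05,
    value_col: str = "psd005",
) -> pd.DataFrame:
    """All pairwise state comparisons within each ROI (or network).

    For each unit and each unordered state pair (a, b) present with at
    least two participants per state, computes the participant-level mean
    difference (state_b - state_a), a pooled-SD two-sample t test and
    Cohen's d.  Significance is Bonferroni-corrected over every emitted
    comparison (164 ROIs x 6 pairs = 984 at full scale).  Pairs a state
    lacks enough observations for are skipped and listed in
    ``result.attrs["skipped"]``.
    """
    rows = []
    skipped = []
    pairs = [(a, b) for i, a in enumerate(STATE_NAMES)
             for b in STATE_NAMES[i + 1:]]
    for unit, sub in psd_table.groupby(by, sort=False):
        groups = {s: g[value_col].to_numpy(dtype=float)
                  for s, g in sub.groupby("state", sort=False)}
        for a, b in pairs:
            xa, xb = groups.get(a), groups.get(b)
            if xa is None or xb is None or xa.size < 2 or xb.size < 2:
                skipped.append((unit, a, b, "state with < 2 observations"))
                continue
            t, p = sps.ttest_ind(xb, xa, equal_var=True)
            rows.append({by: unit, "state_a": a, "state_b": b,
                         "mean_diff": float(xb.mean() - xa.mean()),
                         "cohens_d": cohens_d(xb, xa),
                         "t": float(t), "p_value": float(p),
                         "n_a": int(xa.size), "n_b": int(xb.size)})
    out = pd.DataFrame(rows)
    m = len(out)
    thr = bonferroni_alpha(family_alpha, m) if m else np.nan
    if m:
        out["significant"] = out["p_value"] < thr
    out.attrs["bonferroni_alpha"] = thr
    out.attrs["m_tests"] = m
    out.attrs["skipped"] = skipped
    return out


def perclos_psd_regression(
    perclos_by_participant: dict[str, np.ndarray],
    psd_by_participant: dict[str, np.ndarray],
) -> dict:
    """Pooled OLS of within-participant z-scored psd005 on PERCLOS.

    Each participant contributes a paired second-level series (PERCLOS and
    band power at the same window centres); psd is z-scored within
    participant before pooling so between-participant power offsets do not
    masquerade as a PERCLOS effect.  Returns r2, slope, intercept and p.
    """
    xs, ys = [], []
    for p, perc in perclos_by_participant.items():
        psd = np.asarray(psd_by_participant[p], dtype=float)
        perc = np.asarray(perc, dtype=float)
        if perc.size != psd.size:
            raise ValueError(f"participant {p}: unpaired series")
        keep = np.isfinite(perc) & np.isfinite(psd)
        psd, perc = psd[keep], perc[keep]
        if psd.size < 10:
            continue
        sd = psd.std(ddof=1)
        if sd == 0:
            raise ValueError(f"participant {p}: constant psd series")
        xs.append(perc)
        ys.append((psd - psd.mean()) / sd)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.size < 10:
        raise ValueError("need at least 10 pooled points")
    if np.allclose(x.var(), 0):
        raise ValueError("constant PERCLOS predictor")
    res = sps.linregress(x, y)
    return {"r2": float(res.rvalue**2), "slope": float(res.slope),
            "intercept": float(res.intercept), "p_value": float(res.pvalue),
            "n": int(x.size)}


@dataclass
class NetworkLmmResult:
    """Fixed-effect F tests and per-network post-hoc comparisons."""

    anova: pd.DataFrame              # term, F, df_num, df_den, p_value
    posthoc: pd.DataFrame            # network-level pairwise comparisons
    n_obs: int
    n_participants: int
    ddf_method: str
    converged: bool
    cell_means: pd.DataFrame = field(repr=False, default=None)  # type: ignore

    def summary(self) -> str:
        lines = [f"Linear mixed model on {self.n_obs} participant-network-state "
                 f"cells ({self.n_participants} participants); "
                 f"denominator df: {self.ddf_method}"]
        for _, r in self.anova.iterrows():
            lines.append(f"  {r['term']}: F({r['df_num']:.0f}, {r['df_den']:.2f})"
                         f" = {r['F']:.2f}, p = {r['p_value']:.3g}")
        nsig = int(self.posthoc["significant"].sum()) if len(self.posthoc) else 0
        lines.append(f"  post-hoc: {len(self.posthoc)} comparisons, "
                     f"{nsig} significant at Bonferroni")
        return "\n".join(lines)


def network_lmm(
    psd_table: pd.DataFrame,
    family_alpha: float = 0.05,
    value_col: str = "psd005",
) -> NetworkLmmResult:
    """Mixed model of band power on state x network with participant intercepts.

    ROI values are first averaged into per-(participant, network, state)
    cells.  Fixed effects are state, network and their interaction; the
    random part is an intercept per participant.  Term F statistics are
    Wald chi-square / df_num with a containment-style denominator df
    (n_cells - rank(X) - (n_participants - 1)).  Post-hoc: all state pairs
    within each network (6 x 7 = 42 at full scale), Bonferroni-corrected.
    """
    import statsmodels.formula.api as smf

    if psd_table["participant"].nunique() < 2:
        raise ValueError("random intercept unidentifiable with one participant")
    if psd_table["network"].nunique() < 2:
        raise ValueError("need at least two networks")
    cells = (psd_table.groupby(["participant", "network", "state"], sort=False,
                               as_index=False)[value_col].mean())

    model = smf.mixedlm(f"{value_col} ~ C(state) * C(network)", data=cells,
                        groups=cells["participant"])
    res = model.fit(reml=True)

    design_info = model.data.design_info
    k_fe = len(res.fe_params)
    V = np.asarray(res.cov_params())[:k_fe, :k_fe]
    beta = np.asarray(res.fe_params)
    n_obs = len(cells)
    n_groups = cells["participant"].nunique()
    ddf = n_obs - k_fe - (n_groups - 1)
    rows = []
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = np.arange(k_fe)[sl]
        L = np.zeros((idx.size, k_fe))
        L[np.arange(idx.size), idx] = 1.0
        Lb = L @ beta
        chi2 = float(Lb @ np.linalg.solve(L @ V @ L.T, Lb))
        F = chi2 / idx.size
        rows.append({"term": term, "F": F, "df_num": idx.size,
                     "df_den": float(ddf), "p_value": float(sps.f.sf(F, idx.size, ddf)),
                     "wald_chi2": chi2})
    anova = pd.DataFrame(rows)

    posthoc = pairwise_posthoc(cells.rename(columns={value_col: "psd005"}),
                               by="network", family_alpha=family_alpha,
                               value_col="psd005")
    return NetworkLmmResult(anova=anova, posthoc=posthoc, n_obs=n_obs,
                            n_participants=n_groups,
                            ddf_method="containment (n - rank(X) - (g - 1))",
                            converged=bool(res.converged), cell_means=cells)


@dataclass
class RsqAnovaResult:
    """Two-way ANOVA of state occupancy against self-reported sleep."""

    table: pd.DataFrame
    interaction_F: float
    interaction_p: float
    df_num: float
    df_den: float
    one_way: bool = False

    def summary(self) -> str:
        return (f"state x RSQ interaction: F({self.df_num:.0f}, {self.df_den:.0f})"
                f" = {self.interaction_F:.3f}, p = {self.interaction_p:.3g}")


def rsq_anova(
    occupancy_table: pd.DataFrame, rsq_labels: pd.Series | dict
) -> RsqAnovaResult:
    """Concordance of drowsigram occupancy with RSQ self-report.

    ``occupancy_table`` has one row per (participant, state) with an
    ``occupancy`` column; ``rsq_labels`` maps participant to the reported
    answer (e.g. "slept" / "did_not_sleep").  Runs a two-way ANOVA of
    occupancy on state x report.  Because occupancies sum to one within a
    participant, the report main effect is structurally null and the
    informative term is the interaction (whether the occupancy profile
    differs between report groups); both are in the returned table.  With a
    single report level the model degrades to a one-way ANOVA on state,
    with a warning flag set.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = occupancy_table.copy()
    if isinstance(rsq_labels, dict):
        rsq_labels = pd.Series(rsq_labels)
    df["rsq"] = df["participant"].map(rsq_labels)
    if df["rsq"].isna().any():
        missing = df.loc[df["rsq"].isna(), "participant"].unique()
        raise ValueError(f"participants without RSQ label: {list(missing)[:5]}")

    one_way = df["rsq"].nunique() < 2
    formula = "occupancy ~ C(state)" if one_way else "occupancy ~ C(state) * C(rsq)"
    fit = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    if one_way:
        row = table.loc["C(state)"]
    else:
        row = table.loc["C(state):C(rsq)"]
    return RsqAnovaResult(table=table, interaction_F=float(row["F"]),
                          interaction_p=float(row["PR(>F)"]),
                          df_num=float(row["df"]),
                          df_den=float(table.loc["Residual", "df"]),
                          one_way=one_way)
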