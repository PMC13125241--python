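"""Hierarchical Bayesian linear mixed models with the P+ statistic.

Every contrast family in the analysis guide is a Gaussian linear mixed
model with nested random intercepts (electrode, or electrode pair, grouped
within patient) and weakly informative priors:

* intercept ~ Normal(0, 5), coefficients ~ Normal(0, 2),
* random-effect and residual SDs ~ Exponential(1).

The hierarchy used here is random intercepts only, so there are no
random-effect correlations to put an LKJ prior on.  Posteriors are sampled
with a blocked Gibbs sampler (conjugate normal updates for the
coefficients and random effects, univariate slice steps for the SDs), 4
chains, 5000 iterations with 1000 warmup by default and automatic
escalation to 10000/5000 when Rhat or bulk ESS miss the convergence bar
(Rhat <= 1.01, ESS >= 1000).  Inference is summarized by the posterior
mean, 95% credible interval and P+, the fraction of posterior draws above
zero.  Contrasts fit on log-scale responses can be reported as
multiplicative connectivity ratios by exponentiating draw-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import arviz as az
import numpy as np
import pandas as pd

__all__ = [
    "ModelSpec",
    "PosteriorSummary",
    "HierarchicalFit",
    "ANALYSES",
    "build_model",
    "fit",
    "prob_positive",
    "connectivity_ratio",
    "posterior_predictive_check",
]


@dataclass
class ModelSpec:
    """Declarative model: response, fixed-effect terms, random hierarchy.

    ``fixed`` terms are ("factor", col[, reference_level]), ("numeric", col)
    or ("interaction", col_a, col_b); factors are treatment-coded against
    the reference level (first sorted level by default), numerics
    standardized.  ``random`` lists grouping columns;
    a tuple such as ("patient", "electrode") nests the second factor in the
    first.  ``response_transform`` in {None, "scale", "log_scale", "log",
    "scale_no_center"}.
    """

    analysis_id: str
    response: str
    fixed: list[tuple] = field(default_factory=list)
    random: list = field(default_factory=list)
    response_transform: Optional[str] = None
    exclusions: list[tuple[str, str, object]] = field(default_factory=list)
    prior_intercept_sd: float = 5.0
    prior_coef_sd: float = 2.0
    prior_sd_rate: float = 1.0

    def required_columns(self) -> set[str]:
        cols = {self.response}
        for term in self.fixed:
            cols.update(term[1:3] if term[0] == "interaction" else term[1:2])
        for grp in self.random:
            cols.update((grp,) if isinstance(grp, str) else grp)
        return cols


@dataclass
class PosteriorSummary:
    name: str
    mean: float
    ci_low: float
    ci_high: float
    p_positive: float
    rhat: float
    ess_bulk: float
    converged: bool

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mean <= self.ci_high):
            raise ValueError("credible interval must bracket the mean")


# Analysis guide: contrast families keyed by a descriptive id.  Exclusion
# triples (column, op, value) are applied when the column is present in the
# data; the filters mirror the stated exclusion criteria of each family.
ANALYSES: dict[str, dict] = {
    "behavior_turnaround_by_reward": dict(
        response="turnaround_distance",
        fixed=[("factor", "last_dot_size", "large")],  # coefficient: small > large
        random=["subject"],
        response_transform="log_scale",
        exclusions=[("turned", "==", True), ("conflict", "==", True)],
    ),
    "theta_approach_avoid": dict(
        response="theta_power",
        fixed=[("factor", "period", "avoid")],  # coefficient: approach > avoid
        random=["patient", ("patient", "electrode")],
        response_transform="scale",
        exclusions=[
            ("conflict", "==", True),
            ("attack", "==", False),
            ("dots_collected", ">", 0),
        ],
    ),
    "theta_approach_return_conflict_free": dict(
        response="theta_power",
        fixed=[("factor", "period", "return")],
        random=["patient", ("patient", "electrode")],
        response_transform="scale",
        exclusions=[("conflict", "==", False), ("dots_collected", ">", 0)],
    ),
    "coherence_partner_region": dict(
        response="log_coherence",
        fixed=[("factor", "partner_region")],
        random=["patient", ("patient", "electrode")],
        exclusions=[("conflict", "==", True), ("dots_collected", ">", 0)],
    ),
    "coherence_time": dict(
        response="log_coherence",
        fixed=[("numeric", "time")],
        random=["patient", ("patient", "pair")],
        response_transform="scale",
        exclusions=[("conflict", "==", True), ("cohering_pair", "==", True)],
    ),
    "coherence_time_by_region_pair": dict(
        response="log_coherence",
        fixed=[
            ("numeric", "time"),
            ("factor", "region_pair"),
            ("interaction", "time", "region_pair"),
        ],
        random=["patient", ("patient", "pair")],
        response_transform="scale",
        exclusions=[("conflict", "==", True), ("cohering_pair", "==", True)],
    ),
    "granger_intercept": dict(
        response="net_granger",
        fixed=[],
        random=["patient", ("patient", "pair")],
        response_transform="scale_no_center",
        exclusions=[("conflict", "==", True), ("qualifies", "==", True)],
    ),
    "ccf_intercept": dict(
        response="best_lag",
        fixed=[],
        random=["patient", ("patient", "pair")],
        response_transform="scale_no_center",
        exclusions=[("conflict", "==", True), ("retained", "==", True)],
    ),
    "synchrony_approach_time": dict(
        response="synchrony",
        fixed=[("numeric", "log_approach_time")],
        random=["patient", ("patient", "electrode")],
        response_transform="scale",
        exclusions=[("conflict", "==", True), ("dots_collected", ">", 0)],
    ),
    "hfa_chase_strike": dict(
        response="hfa",
        fixed=[
            ("numeric", "time"),
            ("factor", "attack_kind", "strike"),
            ("interaction", "time", "attack_kind"),
        ],
        random=["patient", ("patient", "electrode")],
        response_transform="scale",
        exclusions=[("attack", "==", True), ("hemisphere", "==", "right")],
    ),
}


def build_model(analysis_id: str, data: pd.DataFrame) -> ModelSpec:
    """Instantiate the model spec for an analysis family against a table.

    Raises on unknown ids and on missing required columns.
    """
    if analysis_id not in ANALYSES:
        raise KeyError(
            f"unknown analysis {analysis_id!r}; known: {sorted(ANALYSES)}"
        )
    spec = ModelSpec(analysis_id=analysis_id, **ANALYSES[analysis_id])
    missing = spec.required_columns() - set(data.columns)
    if missing:
        raise ValueError(f"data table missing columns {sorted(missing)}")
    return spec


def _apply_exclusions(spec: ModelSpec, data: pd.DataFrame) -> pd.DataFrame:
    out = data
    for col, op, val in spec.exclusions:
        if col not in out.columns:
            continue
        if op == "==":
            out = out[out[col] == val]
        elif op == ">":
            out = out[out[col] > val]
        elif op == "!=":
            out = out[out[col] != val]
        else:
            raise ValueError(f"unknown exclusion op {op!r}")
    return out.reset_index(drop=True)


def _encode(spec: ModelSpec, data: pd.DataFrame):
    """Design matrices: X (with intercept), response y, group index arrays."""
    data = _apply_exclusions(spec, data)
    if len(data) == 0:
        raise ValueError("all rows excluded; nothing to model")
    y = np.asarray(data[spec.response], dtype=float)
    tf = spec.response_transform
    if tf in ("log", "log_scale"):
        if np.any(y <= 0):
            raise ValueError("log transform requires positive response")
        y = np.log(y)
    if tf in ("scale", "log_scale"):
        y = (y - y.mean()) / y.std()
    elif tf == "scale_no_center":
        y = y / y.std()

    cols = [np.ones(len(data))]
    names = ["intercept"]

    def factor_codes(
        col: str, reference: Optional[str] = None
    ) -> tuple[list[np.ndarray], list[str]]:
        levels = sorted(pd.unique(data[col].astype(str)))
        if reference is not None:
            if reference not in levels:
                raise ValueError(f"reference level {reference!r} absent from {col!r}")
            levels = [reference] + [lv for lv in levels if lv != reference]
        arrs, labs = [], []
        for lv in levels[1:]:
            arrs.append((data[col].astype(str) == lv).to_numpy(float))
            labs.append(f"{col}[{lv}]")
        return arrs, labs

    def numeric(col: str) -> np.ndarray:
        v = np.asarray(data[col], float)
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else v - v.mean()

    for term in spec.fixed:
        if term[0] == "factor":
            arrs, labs = factor_codes(term[1], term[2] if len(term) > 2 else None)
            cols += arrs
            names += labs
        elif term[0] == "numeric":
            cols.append(numeric(term[1]))
            names.append(term[1])
        elif term[0] == "interaction":
            a, b = term[1], term[2]
            a_num = np.issubdtype(data[a].dtype, np.number)
            base = numeric(a) if a_num else None
            arrs, labs = factor_codes(b)
            for arr, lab in zip(arrs, labs):
                cols.append((base if base is not None else numeric(a)) * arr)
                names.append(f"{a}:{lab}")
        else:
            raise ValueError(f"unknown term kind {term[0]!r}")
    X = np.column_stack(cols)

    groups = []
    for grp in spec.random:
        if isinstance(grp, str):
            key = data[grp].astype(str)
            label = grp
        else:
            key = data[list(grp)].astype(str).agg(":".join, axis=1)
            label = ":".join(grp)
        codes, levels = pd.factorize(key)
        if len(levels) < 2:
            raise ValueError(
                f"random grouping {label!r} has a single level; "
                "the hierarchy needs >= 2 groups"
            )
        groups.append((label, codes, len(levels)))
    return X, y, names, groups


def _slice_sample_sd(
    current: float,
    quad: float,
    m: int,
    rate: float,
    rng: np.random.Generator,
    width: float = 1.0,
) -> float:
    """Univariate slice step on log(sd) for p(sd) ~ Exp(rate), sd of m
    normal deviates with sum of squares ``quad``."""

    def logpost(log_sd: float) -> float:
        sd = np.exp(log_sd)
        return -m * log_sd - 0.5 * quad / sd**2 - rate * sd + log_sd

    x0 = np.log(current)
    y = logpost(x0) + np.log(rng.random() + 1e-300)
    lo, hi = x0 - width * rng.random(), 0.0
    hi = lo + width
    while logpost(lo) > y and x0 - lo < 20:
        lo -= width
    while logpost(hi) > y and hi - x0 < 20:
        hi += width
    for _ in range(100):
        x1 = rng.uniform(lo, hi)
        if logpost(x1) > y:
            return float(np.exp(x1))
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return current


@dataclass
class HierarchicalFit:
    spec: ModelSpec
    coef_names: list[str]
    draws: dict[str, np.ndarray]  # name -> (chains, draws)
    u_draws: list[np.ndarray]  # per group: (chains, draws, n_levels)
    group_labels: list[str]
    X: np.ndarray
    y: np.ndarray
    groups: list[tuple[str, np.ndarray, int]]
    iterations: int
    warmup: int
    escalated: bool

    def summaries(self, convergence_ess: float = 1000.0) -> list[PosteriorSummary]:
        out = []
        for name in self.coef_names:
            d = self.draws[name]
            rhat = float(np.asarray(az.rhat(az.convert_to_dataset(d))["x"]).item())
            ess = float(np.asarray(az.ess(az.convert_to_dataset(d))["x"]).item())
            flat = d.ravel()
            lo, hi = np.percentile(flat, [2.5, 97.5])
            out.append(
                PosteriorSummary(
                    name=name,
                    mean=float(flat.mean()),
                    ci_low=float(lo),
                    ci_high=float(hi),
                    p_positive=prob_positive(flat),
                    rhat=rhat,
                    ess_bulk=ess,
                    converged=bool(rhat <= 1.01 and ess >= convergence_ess),
                )
            )
        return out

    def summary_frame(self, convergence_ess: float = 1000.0) -> pd.DataFrame:
        rows = [s.__dict__ for s in self.summaries(convergence_ess)]
        return pd.DataFrame(rows)

    def coefficient_draws(self, name: str) -> np.ndarray:
        return self.draws[name].ravel()

    def level_prob_positive(self, group_label: str, coef: str = "intercept") -> np.ndarray:
        """Per-level P+ from conditional draws (coefficient + that level's
        random intercept) — the per-electrode significance criterion."""
        gi = self.group_labels.index(group_label)
        u = self.u_draws[gi].reshape(-1, self.u_draws[gi].shape[-1])
        beta = self.draws[coef].ravel()[:, None]
        return (beta + u > 0).mean(axis=0)


def _gibbs(
    X: np.ndarray,
    y: np.ndarray,
    groups: list[tuple[str, np.ndarray, int]],
    prior_sd: np.ndarray,
    rate: float,
    iterations: int,
    warmup: int,
    chains: int,
    seed: int,
) -> tuple[np.ndarray, list[np.ndarray]]:
    n, k = X.shape
    XtX = X.T @ X
    n_keep = iterations - warmup
    beta_out = np.empty((chains, n_keep, k))
    u_out = [np.empty((chains, n_keep, m)) for _, _, m in groups]
    prior_prec = np.diag(1.0 / prior_sd**2)

    for c in range(chains):
        rng = np.random.default_rng(seed + 1000 * c)
        beta = np.zeros(k)
        us = [np.zeros(m) for _, _, m in groups]
        sd_us = [1.0 for _ in groups]
        sigma = max(float(y.std()), 0.1)
        counts = [np.bincount(idx, minlength=m) for _, idx, m in groups]

        for it in range(iterations):
            # random effects contribution
            re_sum = np.zeros(n)
            for (label, idx, m), u in zip(groups, us):
                re_sum += u[idx]
            # beta | rest
            resid = y - re_sum
            prec = XtX / sigma**2 + prior_prec
            mean_rhs = X.T @ resid / sigma**2
            L = np.linalg.cholesky(prec)
            mu = np.linalg.solve(prec, mean_rhs)
            z = rng.standard_normal(k)
            beta = mu + np.linalg.solve(L.T, z)
            fitted_fixed = X @ beta
            # each random block | rest
            for gi, ((label, idx, m), cnt) in enumerate(zip(groups, counts)):
                other = np.zeros(n)
                for gj, (g2, u2) in enumerate(zip(groups, us)):
                    if gj != gi:
                        other += u2[g2[1]]
                r = y - fitted_fixed - other
                s = np.bincount(idx, weights=r, minlength=m)
                post_prec = cnt / sigma**2 + 1.0 / sd_us[gi] ** 2
                post_mean = (s / sigma**2) / post_prec
                us[gi] = post_mean + rng.standard_normal(m) / np.sqrt(post_prec)
                # ASIS translation sweep: exchange location mass between the
                # intercept and this random block (the likelihood only sees
                # their sum), which breaks the slow random walk the two would
                # otherwise perform together.
                tau = m / sd_us[gi] ** 2 + 1.0 / prior_sd[0] ** 2
                delta_mean = (
                    us[gi].sum() / sd_us[gi] ** 2 - beta[0] / prior_sd[0] ** 2
                ) / tau
                delta = delta_mean + rng.standard_normal() / np.sqrt(tau)
                us[gi] -= delta
                beta[0] += delta
                fitted_fixed = X @ beta
                sd_us[gi] = _slice_sample_sd(
                    sd_us[gi], float(np.sum(us[gi] ** 2)), m, rate, rng
                )
            re_sum = np.zeros(n)
            for (label, idx, m), u in zip(groups, us):
                re_sum += u[idx]
            resid = y - fitted_fixed - re_sum
            sigma = _slice_sample_sd(
                sigma, float(resid @ resid), n, rate, rng
            )
            if it >= warmup:
                beta_out[c, it - warmup] = beta
                for gi, u in enumerate(us):
                    u_out[gi][c, it - warmup] = u
    return beta_out, u_out


def fit(
    spec: ModelSpec,
    data: pd.DataFrame,
    seed: int = 0,
    chains: int = 4,
    iterations: int = 5000,
    warmup: int = 1000,
    escalate: bool = True,
    convergence_ess: float = 1000.0,
) -> HierarchicalFit:
    """Fit a hierarchical model by MCMC and return draws with summaries.

    On convergence failure (any fixed effect with Rhat > 1.01 or bulk ESS
    below the bar) the sampler escalates once to 10000 iterations with 5000
    warmup.  Deterministic given (data, seed).
    """
    X, y, names, groups = _encode(spec, data)
    prior_sd = np.full(X.shape[1], spec.prior_coef_sd)
    prior_sd[0] = spec.prior_intercept_sd

    def run(iters: int, warm: int) -> HierarchicalFit:
        beta, u_out = _gibbs(
            X, y, groups, prior_sd, spec.prior_sd_rate, iters, warm, chains, seed
        )
        draws = {name: beta[:, :, i] for i, name in enumerate(names)}
        return HierarchicalFit(
            spec=spec,
            coef_names=names,
            draws=draws,
            u_draws=u_out,
            group_labels=[g[0] for g in groups],
            X=X,
            y=y,
            groups=groups,
            iterations=iters,
            warmup=warm,
            escalated=False,
        )

    result = run(iterations, warmup)
    if escalate and not all(s.converged for s in result.summaries(convergence_ess)):
        result = run(2 * iterations, max(warmup, iterations))
        result.escalated = True
    return result


def prob_positive(draws: np.ndarray) -> float:
    """P+: fraction of posterior draws strictly greater than zero."""
    draws = np.asarray(draws).ravel()
    if draws.size < 1:
        raise ValueError("no draws")
    return float((draws > 0).mean())


def connectivity_ratio(
    contrast_draws: np.ndarray, response_logged: bool = True
) -> dict[str, float]:
    """Multiplicative connectivity-strength ratio for a log-scale contrast.

    Exponentiates the contrast draw-wise and summarizes as a ratio with a
    95% credible interval; a contrast of 0 maps to a ratio of exactly 1.
    """
    if not response_logged:
        raise ValueError("ratio transform requires a log-scale response")
    r = np.exp(np.asarray(contrast_draws, float).ravel())
    lo, hi = np.percentile(r, [2.5, 97.5])
    return {"ratio": float(r.mean()), "ci_low": float(lo), "ci_high": float(hi)}


def posterior_predictive_check(
    fit_result: HierarchicalFit, seed: int = 0, n_rep: int = 500
) -> dict[str, dict[str, float]]:
    """Simulated-vs-observed mean and SD with tail probabilities.

    Draws replicated datasets from the posterior (fixed + random effects +
    residual noise re-sampled) and reports, for each statistic, the
    fraction of replicates at or above the observed value.
    """
    rng = np.random.default_rng(seed)
    X, y, groups = fit_result.X, fit_result.y, fit_result.groups
    beta = np.stack(
        [fit_result.draws[n] for n in fit_result.coef_names], axis=-1
    ).reshape(-1, len(fit_result.coef_names))
    total = beta.shape[0]
    take = rng.choice(total, size=min(n_rep, total), replace=False)
    # Residual SD is re-estimated from the fit residuals at each draw.
    means = np.empty(take.size)
    sds = np.empty(take.size)
    for i, d in enumerate(take):
        mu = X @ beta[d]
        for gi, (label, idx, m) in enumerate(groups):
            u = fit_result.u_draws[gi].reshape(-1, m)[d]
            mu = mu + u[idx]
        resid_sd = np.std(y - mu)
        y_rep = mu + rng.standard_normal(len(y)) * resid_sd
        means[i] = y_rep.mean()
        sds[i] = y_rep.std()
    return {
        "mean": {
            "observed": float(y.mean()),
            "simulated": float(means.mean()),
            "tail_prob": float((means >= y.mean()).mean()),
        },
        "sd": {
            "observed": float(y.std()),
            "simulated": float(sds.mean()),
            "tail_prob": float((sds >= y.std()).mean()),
        },
    }
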