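"""Uncertainty analysis: distribution fitting from means and 95% CIs,
probabilistic sensitivity analysis (PSA), cost-effectiveness acceptability
curves, regression tornado ranking, and univariate sweeps.

Probabilities and utilities are sampled from beta distributions and costs
from gamma distributions, both fitted by the method of moments from a mean
and a 95% interval (SD approximated as the interval width / 3.92).  Because
most published intervals live only in supplementary material, the default
specification assumes an interval of +-20% of the mean for probabilities
and +-50% for costs — declared here and overridable per parameter.

The PSA master seed spawns one counter-based substream per parameter, so
draws are reproducible and earlier draws are unchanged when the draw count
grows.  Per-draw model evaluations use vectorized re-implementations of the
decision tree and Markov engine that are tested for exact agreement with
the reference single-draw code paths.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .markov import (NO_RESPONSE, NONSUICIDE_DEATH, RELAPSE, RESPONSE,
                     SUICIDE_DEATH, fit_mortality_curve, per_cycle_probability)
from .params import ParameterSet, Strategy

__all__ = [
    "Family", "DistributionSpec", "TornadoEntry", "PSAResult",
    "beta_from_mean_ci", "gamma_from_mean_ci", "default_distribution_specs",
    "sample_parameter_set", "run_psa", "ceac", "tornado_regression",
    "univariate_sweep",
]

Z95 = 3.92  # width of a 95% normal interval in SD units


class Family(str, Enum):
    BETA = "BETA"
    GAMMA = "GAMMA"
    TRIANGULAR = "TRIANGULAR"
    FIXED = "FIXED"


@dataclass
class DistributionSpec:
    param_id: str
    family: Family
    mean: float
    lower95: float | None = None
    upper95: float | None = None
    fraction: float | None = None  # triangular half-width as a fraction of the mean


@dataclass
class TornadoEntry:
    param_id: str
    coefficient: float  # standardized regression coefficient
    rank: int


def beta_from_mean_ci(mean: float, lower95: float, upper95: float) -> tuple[float, float]:
    """Method-of-moments beta fit from a mean and 95% interval."""
    if not (0.0 < lower95 <= mean <= upper95 < 1.0):
        raise ValueError(
            f"need 0 < lower95 <= mean <= upper95 < 1, got ({lower95}, {mean}, {upper95})")
    sd = (upper95 - lower95) / Z95
    var = sd * sd
    if var >= mean * (1 - mean):
        raise ValueError(
            f"variance {var:.6g} >= mean(1-mean) = {mean * (1 - mean):.6g}: "
            "no beta distribution matches")
    nu = mean * (1 - mean) / var - 1.0
    return mean * nu, (1 - mean) * nu


def gamma_from_mean_ci(mean: float, lower95: float, upper95: float,
                       min_cv: float = 0.01) -> tuple[float, float]:
    """Method-of-moments gamma fit (shape, scale); a minimum coefficient of
    variation guards the degenerate SD -> 0 limit."""
    if mean <= 0:
        raise ValueError(f"mean must be > 0, got {mean}")
    if not lower95 <= mean <= upper95:
        raise ValueError(
            f"need lower95 <= mean <= upper95, got ({lower95}, {mean}, {upper95})")
    sd = max((upper95 - lower95) / Z95, min_cv * mean)
    shape = (mean / sd) ** 2
    return shape, sd * sd / mean


def default_distribution_specs(ps: ParameterSet, prob_ci_fraction: float = 0.20,
                               cost_ci_fraction: float = 0.50) -> list[DistributionSpec]:
    """The packaged sampling plan over every flat parameter.

    Prevalences, the WTP threshold and the discount rate stay fixed in the
    PSA (the discount rate is explored univariately with a triangular
    distribution instead); probabilities, utilities and per-cycle transition
    probabilities get betas; costs get gammas.  Zero-valued parameters are
    fixed (no spread can be anchored on them).
    """
    specs = []
    for pid, value in sorted(ps.flatten().items()):
        if (pid.startswith("prevalence.") or pid == "wtp"
                or pid == "markov.discount_rate"
                or pid == "utility.suicide_attempt" or value == 0.0):
            specs.append(DistributionSpec(pid, Family.FIXED, value))
        elif pid.startswith("cost."):
            specs.append(DistributionSpec(
                pid, Family.GAMMA, value,
                value * (1 - cost_ci_fraction), value * (1 + cost_ci_fraction)))
        else:  # probability-like: clinical, dispositions, utilities, transitions
            lower = value * (1 - prob_ci_fraction)
            upper = min(value * (1 + prob_ci_fraction), value + (1 - value) / 2)
            specs.append(DistributionSpec(pid, Family.BETA, value, lower, upper))
    return specs


def _draw(spec: DistributionSpec, rng: np.random.Generator, size=None):
    if spec.family == Family.FIXED:
        return spec.mean if size is None else np.full(size, spec.mean)
    if spec.family == Family.BETA:
        a, b = beta_from_mean_ci(spec.mean, spec.lower95, spec.upper95)
        return rng.beta(a, b, size)
    if spec.family == Family.GAMMA:
        shape, scale = gamma_from_mean_ci(spec.mean, spec.lower95, spec.upper95)
        return rng.gamma(shape, scale, size)
    if spec.family == Family.TRIANGULAR:
        f = spec.fraction if spec.fraction is not None else 0.25
        if f <= 0:
            raise ValueError("triangular fraction must be > 0")
        return rng.triangular(spec.mean * (1 - f), spec.mean, spec.mean * (1 + f), size)
    raise ValueError(f"unknown family {spec.family}")


def sample_parameter_set(ps: ParameterSet, specs: list[DistributionSpec],
                         seed: int | np.random.Generator) -> ParameterSet:
    """One sampled parameter set; fixed parameters untouched, sampled
    probabilities clamped to [0, 1], reproducible per seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = ps.flatten()
    updates = {}
    for spec in specs:
        if spec.param_id not in base:
            raise KeyError(f"unknown parameter id {spec.param_id!r}")
        if spec.family == Family.FIXED:
            continue
        val = float(_draw(spec, rng))
        if not spec.param_id.startswith("cost."):
            val = min(max(val, 0.0), 1.0)
        updates[spec.param_id] = val
    return ps.with_values(updates)


def _sample_matrix(specs, n, seed):
    """Per-parameter substreams: {param_id: length-n array} for varying specs."""
    out = {}
    for j, spec in enumerate(sorted(specs, key=lambda s: s.param_id)):
        if spec.family == Family.FIXED:
            continue
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(j,)))
        arr = _draw(spec, rng, n)
        if not spec.param_id.startswith("cost."):
            arr = np.clip(arr, 0.0, 1.0)
        out[spec.param_id] = arr
    return out


# --------------------------------------------------------------- vectorized tree

def _tree_vec(strategy: Strategy, ps: ParameterSet, vals, n):
    """Vectorized twin of tree.strategy_outcomes over n sampled draws."""
    flat = ps.flatten()

    def get(pid):
        return vals.get(pid, flat[pid])

    opts = ps.options
    sc = ps.short_costs
    sv = strategy.value
    disp = {k: get(f"disposition.{sv}.{k}")
            for k in ("switch", "titrate", "observe", "discontinue", "suicide_attempt")}
    p_die = get(f"disposition.{sv}.p_suicide_death_given_attempt")
    rel_ctx = ("switch", "observe", "discontinue", "suicide_attempt")
    nr_ctx = ("switch", "titrate", "observe", "discontinue", "suicide_attempt")
    if opts.renormalize_dispositions:
        rel_sum = sum(disp[k] for k in rel_ctx)
        nr_sum = sum(disp[k] for k in nr_ctx)
    else:
        rel_sum = nr_sum = 1.0
    se_total = sum(get(f"cost.short.side_effect.{name}")
                   for name in sc.side_effect_management)
    lab = get("cost.short.lab_screening")
    consult = get("cost.short.consultation")
    geno = get("cost.short.genotyping_panel")
    ev_rel = get("cost.short.event_relapse")
    ev_sd = get("cost.short.event_suicide_death")
    ev_sa = get("cost.short.event_suicide_attempt")
    ev_surv = get("cost.short.event_survival")

    p_no_se = np.zeros(n)
    p_any_se = np.zeros(n)
    cost = np.zeros(n)
    for gene, gw in opts.gene_weights.items():
        for w_cell, cls, carrier, _cell in ps.cells(strategy, gene):
            w = gw * w_cell
            cb = f"clinical.{sv}.{gene.value}.{cls.value}.{carrier.value}"
            pr = get(f"{cb}.p_response")
            prel = get(f"{cb}.p_relapse_given_response")
            pse = get(f"{cb}.p_side_effect")
            acq_s = strategy if opts.use_dose_reduction else Strategy.SOC
            ab = f"cost.short.acquisition.{gene.value}.{cls.value}.{acq_s.value}"
            acq1 = get(f"{ab}.first_line")
            acqd = get(f"{ab}.discontinuation")
            acqi = get(f"{ab}.increased_dose")
            if sc.alternative_override is not None:
                alt = sc.alternative_override[gene]
            else:
                alt = acq1
            base = acq1 + lab + consult + (geno if strategy == Strategy.PGX else 0.0)

            p_sn = pr * (1 - pse) * (1 - prel)
            p_sa = pr * pse * (1 - prel)
            p_no_se = p_no_se + w * p_sn
            p_any_se = p_any_se + w * (p_sn + p_sa)
            cost = cost + w * (p_sn * base + p_sa * (base + se_total))

            for se_flag, p_branch in ((False, w * pr * (1 - pse) * prel),
                                      (True, w * pr * pse * prel)):
                extra = ev_rel + (se_total if se_flag and opts.charge_relapse_and_se_costs
                                  else 0.0)
                for dname in rel_ctx:
                    p = p_branch * disp[dname] / rel_sum
                    if dname == "switch":
                        cost = cost + p * (base + extra + alt)
                        conv = p
                    elif dname == "observe":
                        cost = cost + p * (base + extra)
                        conv = None
                    elif dname == "discontinue":
                        cost = cost + p * (base + extra + acqd + alt)
                        conv = p
                    else:
                        p_d = p * p_die
                        p_s = p - p_d
                        cost = cost + p_d * (base + extra + ev_sa + ev_sd)
                        cost = cost + p_s * (base + extra + ev_sa + ev_surv + alt)
                        conv = p_s
                    if conv is not None and opts.count_switch_success:
                        if not se_flag:
                            p_no_se = p_no_se + conv
                        p_any_se = p_any_se + conv

            p_nr = w * (1 - pr)
            for dname in nr_ctx:
                p = p_nr * disp[dname] / nr_sum
                if dname == "switch":
                    cost = cost + p * (base + alt)
                    conv = p
                elif dname == "titrate":
                    cost = cost + p * (base + acqi)
                    conv = None
                elif dname == "observe":
                    cost = cost + p * base
                    conv = None
                elif dname == "discontinue":
                    cost = cost + p * (base + acqd + alt)
                    conv = p
                else:
                    p_d = p * p_die
                    p_s = p - p_d
                    cost = cost + p_d * (base + ev_sa + ev_sd)
                    cost = cost + p_s * (base + ev_sa + ev_surv + alt)
                    conv = p_s
                if conv is not None and opts.count_switch_success:
                    p_no_se = p_no_se + conv
                    p_any_se = p_any_se + conv
    return p_no_se, p_any_se, cost


# ------------------------------------------------------------- vectorized Markov

def _markov_vec(strategy: Strategy, ps: ParameterSet, vals, n):
    """Vectorized twin of markov.run_cohort (LY, QALY, total cost arrays)."""
    flat = ps.flatten()

    def get(pid):
        v = vals.get(pid, flat[pid])
        return np.broadcast_to(np.asarray(v, dtype=float), (n,)).copy() \
            if np.ndim(v) == 0 else v

    opts = ps.options
    mk = ps.markov
    sv = strategy.value
    cycle = mk.cycle_years
    max_years = mk.end_age - mk.start_age
    if opts.horizon_years is not None:
        max_years = min(max_years, opts.horizon_years)
    n_cycles = int(round(max_years / cycle))
    rate = mk.discount_rate if opts.discount_on else 0.0

    tb = f"markov.transition.{sv}"
    rel_total = sum(get(f"{tb}.to_relapse.{i}")
                    for i in range(len(mk.transitions[strategy].to_relapse)))
    to_nr = get(f"{tb}.to_no_response")
    to_resp = get(f"{tb}.to_response")
    if mk.variant == "as_printed":
        q_ns_const = get(f"{tb}.nonsuicide_death")
        q_sd_rel = q_sd_nr = get(f"{tb}.suicide_death")
        q_ns_by_cycle = None
    else:
        curve = fit_mortality_curve(mk.mortality_table, mk.mortality_degree)
        ages = mk.start_age + cycle * np.arange(n_cycles)
        eval_ages = ages if opts.age_trends else np.full(n_cycles, mk.start_age)
        q_ns_by_cycle = np.array([
            per_cycle_probability(float(curve(a)), cycle) for a in eval_ages])
        disp = {k: get(f"disposition.{sv}.{k}")
                for k in ("switch", "titrate", "observe", "discontinue",
                          "suicide_attempt")}
        p_die = get(f"disposition.{sv}.p_suicide_death_given_attempt")
        if opts.renormalize_dispositions:
            att_rel = disp["suicide_attempt"] / sum(
                disp[k] for k in ("switch", "observe", "discontinue", "suicide_attempt"))
            att_nr = disp["suicide_attempt"] / sum(
                disp[k] for k in ("switch", "titrate", "observe", "discontinue",
                                  "suicide_attempt"))
        else:
            att_rel = att_nr = disp["suicide_attempt"]
        q_sd_rel = att_rel * p_die
        q_sd_nr = att_nr * p_die

    acq = get(f"cost.long.acquisition.{sv}")
    lab = get("cost.long.lab_screening")
    follow = get("cost.long.follow_up")
    ev_rel = get("cost.long.event_relapse")
    ev_sd = get("cost.long.event_suicide_death")
    ev_sa = get("cost.long.event_suicide_attempt")
    ev_nsd = get("cost.long.event_nonsuicide_death")
    ev_surv = get("cost.long.event_survival")
    u_rel = get("utility.relapse")
    u_nr = get("utility.no_response")
    bands = sorted(ps.utilities.response_by_age)

    def u_resp_at(age):
        band = bands[0]
        for lo in bands:
            if age >= lo:
                band = lo
        return get(f"utility.response.{band}")

    occ = np.zeros((n, 5))
    occ[:, RESPONSE] = 1.0
    ly = np.zeros(n)
    qaly = np.zeros(n)
    cost = np.zeros(n)
    M = np.zeros((n, 5, 5))
    M[:, SUICIDE_DEATH, SUICIDE_DEATH] = 1.0
    M[:, NONSUICIDE_DEATH, NONSUICIDE_DEATH] = 1.0
    for t in range(n_cycles):
        age = mk.start_age + cycle * t
        w = 0.5 if opts.half_cycle and t in (0, n_cycles - 1) else 1.0
        d = w * (1.0 + rate) ** (-cycle * t)
        alive = occ[:, :3].sum(axis=1)
        u = (occ[:, RESPONSE] * u_resp_at(age) + occ[:, RELAPSE] * u_rel
             + occ[:, NO_RESPONSE] * u_nr)
        ly += d * cycle * alive
        qaly += d * cycle * u
        cost += d * (acq + lab + follow) * alive

        q_ns = q_ns_by_cycle[t] if q_ns_by_cycle is not None else q_ns_const
        rows = [
            (RESPONSE, {RELAPSE: rel_total, NO_RESPONSE: to_nr,
                        NONSUICIDE_DEATH: q_ns}),
            (RELAPSE, {RESPONSE: to_resp, SUICIDE_DEATH: q_sd_rel,
                       NONSUICIDE_DEATH: q_ns}),
            (NO_RESPONSE, {RESPONSE: to_resp, SUICIDE_DEATH: q_sd_nr,
                           NONSUICIDE_DEATH: q_ns}),
        ]
        for s, entries in rows:
            total = sum(entries.values()) + np.zeros(n)
            scale = np.where(total > 1.0, 1.0 / np.maximum(total, 1e-300), 1.0)
            for dest, p in entries.items():
                M[:, s, dest] = p * scale
            M[:, s, s] = 1.0 - np.minimum(total, 1.0)

        new_relapse = occ[:, RESPONSE] * M[:, RESPONSE, RELAPSE]
        sd_flow = (occ[:, RELAPSE] * M[:, RELAPSE, SUICIDE_DEATH]
                   + occ[:, NO_RESPONSE] * M[:, NO_RESPONSE, SUICIDE_DEATH]
                   + occ[:, RESPONSE] * M[:, RESPONSE, SUICIDE_DEATH])
        nsd_flow = (occ[:, :3] * M[:, :3, NONSUICIDE_DEATH]).sum(axis=1)
        ev = new_relapse * ev_rel + sd_flow * ev_sd + nsd_flow * ev_nsd
        if mk.variant != "as_printed":
            attempts = occ[:, RELAPSE] * att_rel + occ[:, NO_RESPONSE] * att_nr
            ev = ev + attempts * ev_sa + attempts * (1.0 - p_die) * ev_surv
        cost += d * ev
        occ = np.einsum("ns,nst->nt", occ, M)
    return ly, qaly, cost


@dataclass
class PSAResult:
    draws: pd.DataFrame          # per-draw incremental outcomes
    inputs: pd.DataFrame         # per-draw sampled parameter values
    wtp: float
    seed: int
    base: dict = field(default_factory=dict)

    def summary(self) -> dict[str, float]:
        d = self.draws
        out = {}
        for eff, cost in (("d_p_no_se", "d_cost_short"),
                          ("d_p_any_se", "d_cost_short"),
                          ("d_ly", "d_cost_long"), ("d_qaly", "d_cost_long")):
            dominant = (d[cost] < 0) & (d[eff] > 0)
            acceptable = self.wtp * d[eff] - d[cost] > 0
            out[f"frac_dominant[{eff}]"] = float(dominant.mean())
            out[f"frac_cost_effective[{eff}]"] = float((acceptable & ~dominant).mean())
            out[f"frac_acceptable[{eff}]"] = float(acceptable.mean())
        out["mean_d_cost_short"] = float(d["d_cost_short"].mean())
        out["mean_d_cost_long"] = float(d["d_cost_long"].mean())
        return out


def run_psa(ps: ParameterSet, specs: list[DistributionSpec], n: int,
            seed: int, keep_inputs: bool = True) -> PSAResult:
    """Monte Carlo PSA: n joint draws, each evaluated through both the
    short-term tree and the lifetime Markov model."""
    if n < 1:
        raise ValueError("n must be >= 1")
    known = set(ps.flatten())
    for spec in specs:
        if spec.param_id not in known:
            raise KeyError(f"unknown parameter id {spec.param_id!r}")
    vals = _sample_matrix(specs, n, seed)
    res = {}
    for strat in Strategy:
        p_no, p_any, cost_s = _tree_vec(strat, ps, vals, n)
        ly, qaly, cost_l = _markov_vec(strat, ps, vals, n)
        res[strat] = (p_no, p_any, cost_s, ly, qaly, cost_l)
    pgx, soc = res[Strategy.PGX], res[Strategy.SOC]
    draws = pd.DataFrame({
        "draw": np.arange(n),
        "d_p_no_se": pgx[0] - soc[0],
        "d_p_any_se": pgx[1] - soc[1],
        "d_cost_short": pgx[2] - soc[2],
        "d_ly": pgx[3] - soc[3],
        "d_qaly": pgx[4] - soc[4],
        "d_cost_long": pgx[5] - soc[5],
    })
    draws["dominant_short"] = (draws.d_cost_short < 0) & (draws.d_p_no_se > 0)
    draws["dominant_long"] = (draws.d_cost_long < 0) & (draws.d_qaly > 0)
    inputs = pd.DataFrame(vals) if keep_inputs else pd.DataFrame(index=range(n))
    return PSAResult(draws=draws, inputs=inputs, wtp=ps.wtp, seed=seed)


def ceac(delta_cost, delta_effect, wtp_grid) -> pd.DataFrame:
    """Fraction of draws with positive net monetary benefit at each WTP."""
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    c = np.asarray(delta_cost, dtype=float)
    e = np.asarray(delta_effect, dtype=float)
    if c.size == 0:
        raise ValueError("no draws supplied")
    probs = [(w * e - c > 0).mean() for w in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "p_acceptable": probs})


def tornado_regression(inputs: pd.DataFrame, output) -> list[TornadoEntry]:
    """Rank parameters by standardized OLS coefficients on a PSA output.

    Columns with zero variance are excluded with a warning; remaining inputs
    and the output are z-scored and fitted jointly by least squares.
    """
    y = np.asarray(output, dtype=float)
    cols, X = [], []
    for name in inputs.columns:
        x = inputs[name].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0:
            warnings.warn(f"excluding constant input {name!r} from tornado regression")
            continue
        cols.append(name)
        X.append((x - x.mean()) / sd)
    if len(cols) < 1:
        raise ValueError("need at least one varying input")
    X = np.column_stack(X)
    y_sd = y.std()
    if y_sd == 0:
        raise ValueError("output has zero variance")
    yz = (y - y.mean()) / y_sd
    coef, *_ = np.linalg.lstsq(X, yz, rcond=None)
    order = np.argsort(-np.abs(coef))
    return [TornadoEntry(cols[j], float(coef[j]), rank + 1)
            for rank, j in enumerate(order)]


def univariate_sweep(ps: ParameterSet, param_id: str, evaluate,
                     fraction: float = 0.25) -> tuple[float, float]:
    """Deterministically re-evaluate an endpoint at mean x (1 -+ fraction).

    ``evaluate`` maps a ParameterSet to a scalar endpoint (e.g. the
    short-term saving); returns (result at low value, result at high value).
    """
    flat = ps.flatten()
    if param_id not in flat:
        raise KeyError(f"unknown parameter id {param_id!r}")
    base = flat[param_id]
    low = evaluate(ps.with_values({param_id: base * (1 - fraction)}))
    high = evaluate(ps.with_values({param_id: base * (1 + fraction)}))
    return low, high
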