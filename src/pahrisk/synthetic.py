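"""Seeded synthetic-data generators for the full pipeline.

Three generators emulate the statistical structure the analysis modules
assume, so everything downstream runs and is tested without any field data:

* :func:`generate_congener_profiles` — PM2.5 congener tables built as a
  mixture of hand-built emission-source signatures with day-to-day
  log-normal amplitude variation, a small flat urban baseline and
  per-congener multiplicative noise.  Signature weight vectors are fixtures
  chosen to satisfy their declared diagnostic-ratio bands and to plant
  recoverable factor structure; they are not estimates of real emission
  inventories.
* :func:`generate_population` — subject tables with two-group truncated-
  normal tail moments, Bernoulli lifestyle covariates (with optional
  additive shifts), negative-binomial body weights and school-level PAH
  exposure assignment.
* :func:`generate_risk_inputs` — the study's Monte Carlo configuration per
  group (logistic / log-normal TEQ, negative-binomial body weight, constant
  exposure factors), with documented defaults for the spread parameters the
  configuration leaves free.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotox import COVARIATES
from .profiles import CongenerProfile
from .registry import CONGENERS
from .risk import (DistributionSpec, RiskParams, calibrate_body_weight)
from .sources import RULES, compute_diagnostic_ratios


# ---------------------------------------------------------------------------
# source signatures

@dataclass(frozen=True)
class SourceSignature:
    """One emission source: relative congener weights + target ratio bands.

    ``ratio_bands`` maps a diagnostic-rule name to a half-open ``[lo, hi)``
    interval the signature's noise-free ratio must fall in (the bands that
    diagnose this source; other rules are left undeclared).
    """

    name: str
    weights: dict[str, float]
    ratio_bands: dict[str, tuple[float, float]]

    def __post_init__(self):
        if set(self.weights) != set(CONGENERS):
            raise ValueError(f"{self.name}: weights must cover all congeners")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError(f"{self.name}: weights must be nonnegative")
        total = sum(self.weights.values())
        object.__setattr__(
            self, "weights", {c: w / total for c, w in self.weights.items()})
        unknown = set(self.ratio_bands) - set(RULES)
        if unknown:
            raise ValueError(f"{self.name}: unknown rules {unknown}")
        self._self_check()

    def _self_check(self):
        """Noise-free ratios must fall inside every declared band."""
        ratios = self.noise_free_ratios()
        for rule, (lo, hi) in self.ratio_bands.items():
            v = ratios[rule]
            if not (lo <= v < hi):
                raise AssertionError(
                    f"signature {self.name}: noise-free {rule} = {v:.4f} "
                    f"outside declared band [{lo}, {hi})")

    def noise_free_ratios(self) -> dict[str, float]:
        p = CongenerProfile(sample_id=f"_{self.name}", conc=dict(self.weights))
        return compute_diagnostic_ratios(p)

    def matches(self, ratios: dict[str, float]) -> float:
        """Fraction of this signature's declared bands the ratios satisfy."""
        hits = sum(1 for rule, (lo, hi) in self.ratio_bands.items()
                   if lo <= ratios[rule] < hi)
        return hits / len(self.ratio_bands)


def _sig(name, w, bands):
    return SourceSignature(name, dict(zip(CONGENERS, w)), bands)


# Weight order: NAP ACY ACP FLU PHE ANT FLA PYR BaA CYR BbF BkF BaP IcP DbA BgP
SIGNATURES: dict[str, SourceSignature] = {
    s.name: s for s in (
        _sig("vehicle_exhaust",
             (5, 0.5, 0.5, 5, 2, 0.5, 2, 6, 3.5, 5.5, 6, 1.5, 4, 4, 1, 7.5),
             {"LMW/HMW": (0.0, 1.0), "BaA/CYR": (0.35, math.inf),
              "IcP/(IcP+BgP)": (0.2, 0.5)}),
        _sig("gasoline",
             (2, 0.5, 0.5, 2, 3, 1, 4, 8, 4, 3, 5, 2, 6, 3, 1, 4),
             {"FLU/(FLU+PYR)": (0.0, 0.5), "LMW/HMW": (0.0, 1.0)}),
        _sig("diesel",
             (1, 0.3, 0.3, 8, 2, 0.5, 7, 2, 6, 3, 2, 7, 2, 1.5, 0.5, 2.5),
             {"FLU/(FLU+PYR)": (0.5, math.inf), "LMW/HMW": (0.0, 1.0)}),
        _sig("wood_combustion",
             (2, 0.5, 0.5, 2, 4, 5.5, 1.5, 2, 1, 1, 1.5, 1.5, 2, 2, 5, 1),
             {"ANT/(ANT+PHE)": (0.1, math.inf),
              "IcP/(IcP+BgP)": (0.5, math.inf), "LMW/HMW": (0.0, 1.0)}),
        _sig("coke_oven",
             (8, 0.5, 0.5, 3, 2, 0.5, 1.5, 2, 1, 1.5, 2, 1, 2, 4.5, 0.5, 8.5),
             {"IcP/(IcP+BgP)": (0.2, 0.5), "LMW/HMW": (0.0, 1.0)}),
        _sig("petrogenic",
             (10, 1, 1, 6, 10, 0.6, 2, 3, 0.3, 2.6, 1, 0.5, 1, 0.35, 0.3,
              2.85),
             {"LMW/HMW": (1.0, math.inf), "ANT/(ANT+PHE)": (0.0, 0.1),
              "IcP/(IcP+BgP)": (0.0, 0.2), "BaA/(BaA+CYR)": (0.0, 0.2)}),
    )
}


def best_matching_signature(ratios: dict[str, float],
                            candidates: list[str]) -> str:
    """Candidate signature a sample's diagnostic ratios point to.

    The call works on the discriminating rules — those whose classified
    label differs between candidate signatures; rules on which every
    candidate reads the same anyway carry no information about which one
    dominates and would otherwise drown out the markers (ratios mix
    non-linearly).  Each discriminating rule votes for the candidates whose
    expected label matches the sample's label; ties are broken by
    root-mean-square log-ratio distance on those rules (ratios are
    scale-free and positive, so the log metric treats 0.2-vs-0.4 like
    1-vs-2).  Undefined (NaN) ratios are skipped.
    """
    from .sources import classify_source  # local to avoid cycle at import

    refs = {name: SIGNATURES[name].noise_free_ratios() for name in candidates}
    rules = [r for r in RULES
             if len({classify_source(r, refs[n][r]) for n in candidates}) > 1]
    if not rules:
        rules = list(RULES)

    votes = {name: 0 for name in candidates}
    for r in rules:
        if math.isnan(ratios[r]):
            continue
        label = classify_source(r, ratios[r])
        for name in candidates:
            if classify_source(r, refs[name][r]) == label:
                votes[name] += 1
    top = max(votes.values())
    tied = [n for n in candidates if votes[n] == top]
    if len(tied) == 1:
        return tied[0]

    def dist(name: str) -> float:
        ref = refs[name]
        terms = [(math.log(ratios[r]) - math.log(ref[r])) ** 2
                 for r in rules
                 if not math.isnan(ratios[r]) and ratios[r] > 0]
        if not terms:
            return math.inf
        return math.sqrt(sum(terms) / len(terms))

    return min(tied, key=lambda name: (dist(name), name))


#: (dominant, minor) source pairs that the six diagnostic rules are able to
#: separate when the dominant source carries the marker load: the gasoline/
#: diesel contrast rests on FLU/(FLU+PYR), fuel- vs biomass-combustion on
#: IcP/(IcP+BgP), and pyrogenic vs petrogenic on the LMW/ANT/BaA rules.
#: Petroleum-dominant mixtures with a combustion admixture are deliberately
#: absent: combustion congeners dominate the marker ratios even as a minor
#: mass fraction, a documented failure mode of ratio diagnostics.
SEPARABLE_MIXTURES: tuple[tuple[str, str], ...] = (
    ("gasoline", "diesel"), ("diesel", "gasoline"),
    ("diesel", "vehicle_exhaust"), ("vehicle_exhaust", "wood_combustion"),
    ("wood_combustion", "diesel"), ("coke_oven", "wood_combustion"),
    ("gasoline", "wood_combustion"), ("vehicle_exhaust", "petrogenic"),
    ("gasoline", "petrogenic"), ("diesel", "petrogenic"),
    ("wood_combustion", "petrogenic"), ("coke_oven", "petrogenic"),
)


def _lognormal_unit_mean(rng, sigma_or_cv, n, from_cv=False):
    s2 = math.log1p(sigma_or_cv**2) if from_cv else sigma_or_cv**2
    return rng.lognormal(-s2 / 2.0, math.sqrt(s2), n)


def generate_congener_profiles(mixture: dict[str, float], n: int,
                               noise_sd: float = 0.2, seed: int = 0, *,
                               total_mean: float = 60.0,
                               day_cv: float = 0.5,
                               baseline_frac: float = 0.03,
                               floor_sd: float = 0.0,
                               mdl: float = 0.1,
                               school: str = "S1", zone: str = "exposed",
                               site: str = "outdoor",
                               return_contributions: bool = False):
    """Synthetic congener profiles from a mixture of source signatures.

    Each sample k and congener i gets

        conc[k, i] = total_mean x [ (1-b) * sum_s f_s w_si A_sk + b u_i ]
                     x eps_ki

    with per-signature day-to-day amplitudes ``A_sk`` (log-normal, unit
    mean, coefficient of variation ``day_cv``, independent across
    signatures and days), a flat baseline ``u`` of mass ``baseline_frac``,
    and unit-mean log-normal per-congener noise with log-sd ``noise_sd``.
    ``floor_sd > 0`` adds an absolute Gaussian measurement floor (ng m-3,
    clipped at 0) emulating near-detection-limit instrument noise, which
    makes minor congeners relatively noisier — the regime in which signature
    congeners dominate factor loadings.  Concentrations below ``mdl`` are
    censored to missing (non-detects), so downstream MDL/2 imputation is
    exercised.

    With ``return_contributions=True`` also returns the realized per-sample
    source contributions ``f_s A_sk`` (a DataFrame, one column per
    signature), whose argmax is the source that actually dominated each
    sample's emissions that day.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    fracs = np.array(list(mixture.values()), dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-6:
        raise ValueError(f"mixture fractions sum to {fracs.sum()}, not 1")
    unknown = set(mixture) - set(SIGNATURES)
    if unknown:
        raise ValueError(f"unknown signatures {unknown}")
    rng = np.random.default_rng(seed)
    W = np.array([[SIGNATURES[s].weights[c] for c in CONGENERS]
                  for s in mixture])                      # (n_sig, 16)
    amps = np.column_stack([
        _lognormal_unit_mean(rng, day_cv, n, from_cv=True)
        for _ in mixture])                                # (n, n_sig)
    signal = (amps * fracs) @ W                           # (n, 16)
    baseline = np.full(len(CONGENERS), 1.0 / len(CONGENERS))
    # the flat baseline tracks overall source activity, so its share of a
    # sample stays ~baseline_frac on low- and high-emission days alike
    activity = (amps * fracs).sum(axis=1, keepdims=True)
    mean_part = (1 - baseline_frac) * signal + baseline_frac * activity * baseline
    eps = _lognormal_unit_mean(rng, noise_sd, (n, len(CONGENERS)))
    conc = total_mean * mean_part * eps
    if floor_sd > 0:
        conc = np.clip(conc + rng.normal(0.0, floor_sd, conc.shape), 0.0,
                       None)
    profiles = []
    for k in range(n):
        row = {c: (None if conc[k, i] < mdl else float(conc[k, i]))
               for i, c in enumerate(CONGENERS)}
        profiles.append(CongenerProfile(
            sample_id=f"{school}-{site}-{k:03d}", school=school, zone=zone,
            site=site, conc=row, mdl={c: mdl for c in CONGENERS}))
    if return_contributions:
        contrib = pd.DataFrame(amps * fracs, columns=list(mixture))
        return profiles, contrib
    return profiles


# ---------------------------------------------------------------------------
# study configuration (group-level risk inputs)

#: Printed group-level study constants used as generator/config inputs.
STUDY = {
    "exposed": {
        "school_teq": {"S1": 20.01, "S3": 16.89, "S2": 13.69},
        "teq_mean": 17.35,
        "nb_p": 0.206,
        "group_mean_ilcr": 1.13e-6,
        "outdoor_total": {"S1": 64.64, "S2": 67.72, "S3": 61.60},
        "indoor_total": {"S1": 63.22, "S2": 54.97, "S3": 44.27},
    },
    "comparative": {
        "school_teq": {"C1": 5.51, "C2": 0.54, "C3": 0.21},
        "teq_mean": 2.21, "teq_sd": 2.51,
        "nb_p": 0.307,
        "group_mean_ilcr": 1.6e-7,
        "outdoor_total": {"C1": 35.06, "C2": 5.93, "C3": 6.36},
        "indoor_total": {"C1": 13.09, "C2": 4.65, "C3": 4.24},
    },
}

#: Fraction of a school's total PAHs attributed to the seven probable
#: carcinogens when only totals are configured (synthetic default).
CARCINOGEN_FRACTION = 0.45


def logistic_scale_from_values(values) -> float:
    """Logistic scale matching the sample sd of a few observed means.

    The logistic sd is scale x pi/sqrt(3); inverting gives
    scale = sd x sqrt(3)/pi.  Used to default the unprinted spread of the
    exposed-group TEQ distribution from the three school TEQs.
    """
    sd = float(np.std(np.asarray(values, dtype=float), ddof=1))
    return sd * math.sqrt(3.0) / math.pi


def calibrated_group_bw(group: str) -> float:
    """Group body weight from inverting the risk model at group-mean TEQ."""
    cfg = STUDY[group]
    return calibrate_body_weight(cfg["teq_mean"], cfg["group_mean_ilcr"])


def nb_r_for_mean(mean: float, p: float) -> float:
    """Negative-binomial r with the given mean at success probability p."""
    if mean <= 0:
        raise ValueError("mean must be > 0")
    return mean * p / (1.0 - p)


def generate_risk_inputs(group: str,
                         ) -> tuple[DistributionSpec, DistributionSpec,
                                    RiskParams]:
    """Monte Carlo configuration (teq_spec, bw_spec, params) for a group.

    Exposed: logistic TEQ at mean 17.35 with scale defaulted from the
    dispersion of the three school TEQs; comparative: log-normal TEQ with
    arithmetic moments (2.21, 2.51).  Body weight is negative-binomial at
    the printed p, with r defaulted so the distribution mean equals the
    group body weight calibrated from the deterministic group-mean risk.
    """
    if group not in STUDY:
        raise ValueError(f"unknown group {group!r}")
    cfg = STUDY[group]
    if group == "exposed":
        teq_spec = DistributionSpec(
            "TEQ", "logistic",
            {"mean": cfg["teq_mean"],
             "scale": logistic_scale_from_values(
                 list(cfg["school_teq"].values()))})
    else:
        teq_spec = DistributionSpec(
            "TEQ", "lognormal_arithmetic",
            {"mean": cfg["teq_mean"], "sd": cfg["teq_sd"]})
    bw = calibrated_group_bw(group)
    bw_spec = DistributionSpec(
        "BW", "negative_binomial",
        {"p": cfg["nb_p"], "r": nb_r_for_mean(bw, cfg["nb_p"])})
    return teq_spec, bw_spec, RiskParams(BW=bw)


# ---------------------------------------------------------------------------
# population generator

@dataclass(frozen=True)
class PopulationSpec:
    """Two-group subject population specification.

    Tail moments are truncated-normal (>= 0) at the group mean/sd; additive
    covariate shifts move carriers of a covariate while the base level is
    recentred so the group mean stays on target.  Prevalences and shifts
    beyond the mosquito-coil effect are synthetic defaults.
    """

    n_exposed: int = 85
    n_comparative: int = 120
    tail_mean: dict[str, float] = field(
        default_factory=lambda: {"exposed": 27.20, "comparative": 21.03})
    tail_sd: dict[str, float] = field(
        default_factory=lambda: {"exposed": 8.21, "comparative": 4.88})
    prevalence: dict[str, float] = field(
        default_factory=lambda: {"tobacco_smoke": 0.40, "grilled_food": 0.50,
                                 "supplement": 0.50, "mosquito_coil": 0.15,
                                 "open_burning": 0.30})
    shift: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "exposed": {"mosquito_coil": 3.34},
            "comparative": {"mosquito_coil": 2.07}})

    def __post_init__(self):
        if self.n_exposed < 2 or self.n_comparative < 2:
            raise ValueError("need n >= 2 per group")
        if any(sd <= 0 for sd in self.tail_sd.values()):
            raise ValueError("tail-moment sds must be > 0")
        if any(not 0 <= q <= 1 for q in self.prevalence.values()):
            raise ValueError("prevalences must lie in [0, 1]")


def generate_population(spec: PopulationSpec | None = None,
                        seed: int = 0) -> pd.DataFrame:
    """Synthetic subject table for both groups.

    Columns: the subject schema (id, group, school, age, sex, bmi, body
    weight, tail moment, five 0/1 covariates) plus the four school-level
    exposure assignments used by the prediction models.
    """
    spec = spec or PopulationSpec()
    rng = np.random.default_rng(seed)
    frames = []
    for group, n in (("exposed", spec.n_exposed),
                     ("comparative", spec.n_comparative)):
        cfg = STUDY[group]
        schools = sorted(cfg["school_teq"])
        cov = {k: (rng.random(n) < spec.prevalence[k]).astype(int)
               for k in COVARIATES}
        shifts = spec.shift.get(group, {})
        shift_term = sum(cov[k] * v for k, v in shifts.items())
        # recentre so the group mean stays on target despite the shifts
        base = (spec.tail_mean[group]
                - sum(spec.prevalence[k] * v for k, v in shifts.items()))
        mu = np.full(n, float(base)) + shift_term
        sd = spec.tail_sd[group]
        a = (0.0 - mu) / sd  # lower truncation at 0 in standard units
        tail = stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=n,
                                   random_state=rng)
        school = rng.choice(schools, size=n)
        bw_spec = generate_risk_inputs(group)[1]
        bwp = bw_spec.params
        bw = np.maximum(
            rng.negative_binomial(bwp["r"], bwp["p"], n).astype(float), 1.0)
        df = pd.DataFrame({
            "subject_id": [f"{group[:3]}-{i:03d}" for i in range(n)],
            "group": group,
            "school": school,
            "age": rng.integers(9, 12, n),
            "sex": rng.choice(["F", "M"], size=n),
            "bmi": np.round(rng.normal(16.5, 2.5, n).clip(11, 35), 1),
            "body_weight_kg": bw,
            "tail_moment": tail,
            **cov,
        })
        df["total_outdoor_pahs"] = df["school"].map(cfg["outdoor_total"])
        df["total_indoor_pahs"] = df["school"].map(cfg["indoor_total"])
        df["carcinogen_outdoor_pahs"] = (CARCINOGEN_FRACTION
                                         * df["total_outdoor_pahs"])
        df["carcinogen_indoor_pahs"] = (CARCINOGEN_FRACTION
                                        * df["total_indoor_pahs"])
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
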