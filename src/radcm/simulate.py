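"""Synthetic binary case tables from a latent-syndrome noisy-OR model.

Generative model, per case:

1. Syndromes are drawn in topological order of the (acyclic) syndrome
   link graph. A syndrome with no present parent uses its base
   prevalence; when one or more parents are present it activates by a
   noisy-OR over the present parents' link probabilities, so the
   conditional given a single parent equals the configured link
   probability exactly.
2. Symptom *s* activates with probability
   ``1 - (1 - eps_s) * prod_k (1 - E[k][s])`` over the present syndromes
   *k* (noisy-OR with background/leak rate ``eps_s``).

Symptoms are conditionally independent given the syndrome state, which
makes every population quantity the association analysis estimates —
symptom marginals, directed pairwise conditionals P(j | i), and
symptom-given-syndrome conditionals — computable in closed form by
enumerating the 2^K syndrome states (K <= 12; a seeded Monte-Carlo
estimate is recorded beyond that). Shared latent parents between a rare
and a common symptom produce exactly the asymmetric one-way patterns the
RAD analysis is designed to detect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from graphlib import TopologicalSorter, CycleError
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .data_model import CaseTable

_ENUMERATION_LIMIT = 12  # 2^K states; beyond this, Monte-Carlo


@dataclass
class SimulationConfig:
    """Full specification of the generative model.

    syndromes
        ``(name, prevalence)`` pairs; prevalence is the activation
        probability when no linked parent is present.
    syndrome_links
        Directed ``(source, target, probability)`` triples; must be
        acyclic. Induce syndrome co-occurrence and one-way syndrome
        links.
    symptoms
        ``(name, background_rate)`` pairs (the noisy-OR leak).
    emissions
        K x S matrix; ``emissions[k][s]`` is the probability that
        syndrome *k*, when present, activates symptom *s*.
    """

    n_cases: int
    syndromes: list[tuple[str, float]]
    syndrome_links: list[tuple[str, str, float]]
    symptoms: list[tuple[str, float]]
    emissions: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.emissions = np.asarray(self.emissions, dtype=float)
        k, s = len(self.syndromes), len(self.symptoms)
        if self.emissions.shape != (k, s):
            raise ValueError(
                f"emissions must be K x S = {k} x {s}, got {self.emissions.shape}"
            )
        if self.n_cases < 1:
            raise ValueError("n_cases must be positive")
        names = [n for n, _ in self.syndromes] + [n for n, _ in self.symptoms]
        if len(set(names)) != len(names):
            raise ValueError("syndrome and symptom names must be unique")
        for label, probs in (
            ("syndrome prevalence", [p for _, p in self.syndromes]),
            ("symptom background", [p for _, p in self.symptoms]),
            ("link probability", [p for _, _, p in self.syndrome_links]),
        ):
            arr = np.asarray(probs, dtype=float)
            if arr.size and ((arr < 0) | (arr > 1)).any():
                raise ValueError(f"{label} values must lie in [0, 1]")
        if ((self.emissions < 0) | (self.emissions > 1)).any():
            raise ValueError("emission probabilities must lie in [0, 1]")
        known = {n for n, _ in self.syndromes}
        for src, dst, _ in self.syndrome_links:
            if src not in known or dst not in known:
                raise ValueError(f"link {src!r} -> {dst!r} names unknown syndrome")
        self.topological_order()  # raises on cycles

    @property
    def syndrome_names(self) -> list[str]:
        return [n for n, _ in self.syndromes]

    @property
    def symptom_names(self) -> list[str]:
        return [n for n, _ in self.symptoms]

    def topological_order(self) -> list[int]:
        """Indices of syndromes in parent-before-child order."""
        ts = TopologicalSorter({n: set() for n in self.syndrome_names})
        for src, dst, _ in self.syndrome_links:
            ts.add(dst, src)
        try:
            order = list(ts.static_order())
        except CycleError as e:
            raise ValueError(f"syndrome_links contain a cycle: {e.args[1]}") from None
        idx = {n: i for i, n in enumerate(self.syndrome_names)}
        return [idx[n] for n in order]

    def to_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "syndromes": [[n, float(p)] for n, p in self.syndromes],
            "syndrome_links": [[a, b, float(p)] for a, b, p in self.syndrome_links],
            "symptoms": [[n, float(p)] for n, p in self.symptoms],
            "emissions": self.emissions.tolist(),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(
            n_cases=int(d["n_cases"]),
            syndromes=[(str(n), float(p)) for n, p in d["syndromes"]],
            syndrome_links=[(str(a), str(b), float(p)) for a, b, p in d["syndrome_links"]],
            symptoms=[(str(n), float(p)) for n, p in d["symptoms"]],
            emissions=np.asarray(d["emissions"], dtype=float),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if str(path).endswith(".json"):
            path.write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")
        else:
            path.write_text(yaml.safe_dump(self.to_dict()), encoding="utf-8")


@dataclass
class GroundTruth:
    """Exact (or recorded Monte-Carlo) population quantities of a config.

    Arrays are ordered like the config's syndrome/symptom lists.
    ``symptom_conditional[i][j]`` is the true P(symptom j = 1 | symptom
    i = 1); ``symptom_given_syndrome[k][s]`` is P(symptom s = 1 |
    syndrome k = 1).
    """

    config: SimulationConfig
    syndrome_marginals: np.ndarray
    symptom_marginals: np.ndarray
    symptom_conditional: np.ndarray
    symptom_given_syndrome: np.ndarray
    syndrome_conditional: np.ndarray
    method: str = "enumeration"
    mc_seed: Optional[int] = None
    mc_samples: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "mc_seed": self.mc_seed,
            "mc_samples": self.mc_samples,
            "syndrome_names": self.config.syndrome_names,
            "symptom_names": self.config.symptom_names,
            "syndrome_marginals": self.syndrome_marginals.tolist(),
            "symptom_marginals": self.symptom_marginals.tolist(),
            "symptom_conditional": self.symptom_conditional.tolist(),
            "symptom_given_syndrome": self.symptom_given_syndrome.tolist(),
            "syndrome_conditional": self.syndrome_conditional.tolist(),
            "config": self.config.to_dict(),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True), encoding="utf-8"
        )


def _conditional_activation(
    config: SimulationConfig, Z: np.ndarray, k: int
) -> np.ndarray:
    """P(syndrome k = 1 | parent states in rows of Z)."""
    base = config.syndromes[k][1]
    name = config.syndrome_names[k]
    idx = {n: i for i, n in enumerate(config.syndrome_names)}
    parents = [(idx[src], p) for src, dst, p in config.syndrome_links if dst == name]
    if not parents:
        return np.full(Z.shape[0], base)
    miss = np.ones(Z.shape[0])
    any_parent = np.zeros(Z.shape[0], dtype=bool)
    for pi, p in parents:
        on = Z[:, pi] == 1
        miss = np.where(on, miss * (1.0 - p), miss)
        any_parent |= on
    return np.where(any_parent, 1.0 - miss, base)


def _state_distribution(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """All 2^K syndrome states and their exact probabilities."""
    k = len(config.syndromes)
    states = ((np.arange(2 ** k)[:, None] >> np.arange(k)[None, :]) & 1).astype(np.int8)
    probs = np.ones(2 ** k)
    for j in config.topological_order():
        pk = _conditional_activation(config, states, j)
        probs *= np.where(states[:, j] == 1, pk, 1.0 - pk)
    return states, probs


def _symptom_activation(config: SimulationConfig, Z: np.ndarray) -> np.ndarray:
    """P(symptom s = 1 | syndrome state), rows of Z -> (len(Z), S)."""
    eps = np.array([b for _, b in config.symptoms])
    # product over present syndromes of (1 - E[k, s])
    miss = np.prod(
        np.where(Z[:, :, None] == 1, 1.0 - config.emissions[None, :, :], 1.0), axis=1
    )
    return 1.0 - (1.0 - eps)[None, :] * miss


def _truth_from_states(
    config: SimulationConfig, states: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, ...]:
    ps = _symptom_activation(config, states)  # (states, S)
    w = weights / weights.sum()
    syn_marg = w @ states
    sym_marg = w @ ps
    joint = ps.T @ (w[:, None] * ps)  # P(i & j), i != j
    np.fill_diagonal(joint, sym_marg)
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.where(sym_marg[:, None] > 0, joint / sym_marg[:, None], 0.0)
    np.fill_diagonal(cond, 0.0)

    k = states.shape[1]
    sym_given_syn = np.zeros((k, ps.shape[1]))
    syn_joint = states.T @ (w[:, None] * states)
    np.fill_diagonal(syn_joint, syn_marg)
    for j in range(k):
        mask = states[:, j] == 1
        if syn_marg[j] > 0:
            sym_given_syn[j] = (w[mask] @ ps[mask]) / syn_marg[j]
    with np.errstate(divide="ignore", invalid="ignore"):
        syn_cond = np.where(syn_marg[:, None] > 0, syn_joint / syn_marg[:, None], 0.0)
    np.fill_diagonal(syn_cond, 0.0)
    return syn_marg, sym_marg, cond, sym_given_syn, syn_cond


def ground_truth(
    config: SimulationConfig, mc_samples: int = 100_000, mc_seed: int = 0
) -> GroundTruth:
    """True marginals and conditionals implied by ``config``.

    Exact enumeration over the 2^K syndrome states for K <= 12;
    otherwise a Monte-Carlo estimate over syndrome states with the
    recorded seed and sample size.
    """
    k = len(config.syndromes)
    if k <= _ENUMERATION_LIMIT:
        states, probs = _state_distribution(config)
        vals = _truth_from_states(config, states, probs)
        return GroundTruth(config, *vals)
    rng = np.random.default_rng(mc_seed)
    Z = _draw_syndromes(config, mc_samples, rng)
    vals = _truth_from_states(config, Z, np.ones(mc_samples))
    return GroundTruth(
        config, *vals, method="monte_carlo", mc_seed=mc_seed, mc_samples=mc_samples
    )


def _draw_syndromes(
    config: SimulationConfig, n: int, rng: np.random.Generator
) -> np.ndarray:
    k = len(config.syndromes)
    Z = np.zeros((n, k), dtype=np.int8)
    for j in config.topological_order():
        pj = _conditional_activation(config, Z, j)
        Z[:, j] = rng.random(n) < pj
    return Z


def simulate(
    config: SimulationConfig, *, with_truth: bool = True
) -> tuple[CaseTable, Optional[GroundTruth]]:
    """Draw a case table from the model; reproducible given the seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    Z = _draw_syndromes(config, n, rng)
    p_sym = _symptom_activation(config, Z)
    F = (rng.random(p_sym.shape) < p_sym).astype(np.int8)
    table = CaseTable(
        case_ids=[str(i) for i in range(1, n + 1)],
        symptom_names=config.symptom_names,
        syndrome_names=config.syndrome_names,
        F=F,
        L=Z,
    )
    return table, (ground_truth(config) if with_truth else None)


# ---------------------------------------------------------------------------
# CHD-shaped preset
# ---------------------------------------------------------------------------

#: Target marginal frequencies for the ten syndromes (base rates are
#: back-calculated so that the linked model reproduces these exactly).
_SYNDROME_TARGETS: dict[str, float] = {
    "heart_qi_deficiency": 0.609,
    "heart_yang_deficiency": 0.314,
    "heart_yin_deficiency": 0.386,
    "heart_blood_deficiency": 0.029,
    "turbid_phlegm": 0.483,
    "blood_stasis": 0.760,
    "qi_stagnation": 0.207,
    "heart_fire_hyperactivity": 0.054,
    "heart_kidney_yang_deficiency": 0.117,
    "cardiopulmonary_qi_deficiency": 0.025,
}

#: Directed syndrome dependencies: (source, target, P(target | source
#: present)). blood_stasis co-occurs strongly with heart_qi_deficiency
#: (a two-way pair ~0.80/0.64); heart_kidney_yang_deficiency is almost
#: always accompanied by heart_yang_deficiency (~0.97 one direction,
#: 0.36 the other).
_SYNDROME_LINKS: list[tuple[str, str, float]] = [
    ("heart_qi_deficiency", "blood_stasis", 0.80),
    ("heart_yang_deficiency", "heart_kidney_yang_deficiency", 0.36),
]

#: Target marginal frequencies for the 63 symptoms, spanning ~0.002-0.79.
_SYMPTOM_TARGETS: dict[str, float] = {
    "chills": 0.350,
    "cold_limbs": 0.220,
    "dampness_heat": 0.100,
    "feverish_palms_and_soles": 0.150,
    "spontaneous_sweating": 0.391,
    "night_sweat": 0.362,
    "palpitation": 0.645,
    "chest_distress": 0.786,
    "chest_pain": 0.486,
    "short_breath": 0.697,
    "edema": 0.180,
    "hypodynamia": 0.654,
    "dysphoria": 0.404,
    "paroxysmal_night_dyspnea": 0.027,
    "amnesia": 0.200,
    "dizziness": 0.485,
    "tinnitus": 0.351,
    "mouth_and_tongue_sore": 0.080,
    "cough": 0.326,
    "cough_with_sputum": 0.254,
    "hiccup": 0.060,
    "acid_regurgitation": 0.090,
    "gastric_stuffiness": 0.120,
    "gastralgia": 0.070,
    "epigastric_upset": 0.050,
    "nausea_and_vomiting": 0.080,
    "heavy_breathing": 0.100,
    "lateral_thorax_distending_pain": 0.031,
    "abdomen_distending_pain": 0.090,
    "soreness_weakness_waist_knees": 0.508,
    "numbness_of_hands_and_feet": 0.371,
    "body_soreness": 0.110,
    "thirsty_and_dry_pharynx": 0.486,
    "absence_of_thirst": 0.130,
    "fluid_failing_resolve_thirst": 0.036,
    "like_cold_drink": 0.259,
    "like_hot_drink": 0.140,
    "poor_appetite": 0.240,
    "always_hungry": 0.022,
    "hunger_without_desire_to_eat": 0.011,
    "bitter_taste": 0.170,
    "mucosity_in_mouth": 0.048,
    "tastelessness_in_mouth": 0.064,
    "loose_stool": 0.120,
    "water_like_stool": 0.014,
    "diarrhea_with_undigested_food": 0.014,
    "diarrhea_in_the_morning": 0.009,
    "stool_sloppy_or_bound": 0.016,
    "constipation": 0.230,
    "dry_stool_like_sheep_feces": 0.050,
    "non_smooth_defecation": 0.013,
    "clear_urine_large_amounts": 0.058,
    "dark_urine": 0.088,
    "frequent_micturition": 0.210,
    "deficient_urine": 0.070,
    "stranguria": 0.025,
    "urinating_burning_heat": 0.002,
    "dribble_of_urine": 0.020,
    "frequent_night_urination": 0.295,
    "aggravating_gloom": 0.434,
    "sleepiness": 0.007,
    "impetuosity_rage": 0.323,
    "easily_frightened": 0.160,
}

#: Hand-designed emission probabilities (syndrome activates symptom).
#: Cardinal symptoms (chest distress, palpitation, short breath) are
#: driven by several syndromes; yang-deficiency syndromes drive chills
#: and cold limbs; yin deficiency drives night sweat; the rare
#: paroxysmal night dyspnea is emitted only by heart_yang_deficiency,
#: planting a one-way pair toward palpitation.
_EMISSIONS: dict[tuple[str, str], float] = {
    ("blood_stasis", "chest_distress"): 0.55,
    ("heart_qi_deficiency", "chest_distress"): 0.45,
    ("turbid_phlegm", "chest_distress"): 0.40,
    ("heart_qi_deficiency", "short_breath"): 0.50,
    ("cardiopulmonary_qi_deficiency", "short_breath"): 0.80,
    ("heart_yang_deficiency", "short_breath"): 0.40,
    ("heart_qi_deficiency", "hypodynamia"): 0.60,
    ("heart_yang_deficiency", "hypodynamia"): 0.30,
    ("heart_qi_deficiency", "palpitation"): 0.45,
    ("heart_yang_deficiency", "palpitation"): 0.75,
    ("heart_kidney_yang_deficiency", "soreness_weakness_waist_knees"): 0.85,
    ("heart_blood_deficiency", "soreness_weakness_waist_knees"): 0.60,
    ("heart_yin_deficiency", "soreness_weakness_waist_knees"): 0.35,
    ("blood_stasis", "chest_pain"): 0.45,
    ("heart_yin_deficiency", "thirsty_and_dry_pharynx"): 0.60,
    ("heart_yin_deficiency", "dizziness"): 0.40,
    ("turbid_phlegm", "dizziness"): 0.35,
    ("qi_stagnation", "aggravating_gloom"): 0.70,
    ("heart_fire_hyperactivity", "dysphoria"): 0.80,
    ("heart_yin_deficiency", "dysphoria"): 0.40,
    ("heart_qi_deficiency", "spontaneous_sweating"): 0.35,
    ("heart_yang_deficiency", "spontaneous_sweating"): 0.30,
    ("blood_stasis", "numbness_of_hands_and_feet"): 0.30,
    ("heart_yin_deficiency", "night_sweat"): 0.65,
    ("cardiopulmonary_qi_deficiency", "night_sweat"): 0.50,
    ("heart_kidney_yang_deficiency", "tinnitus"): 0.50,
    ("heart_yin_deficiency", "tinnitus"): 0.30,
    ("heart_yang_deficiency", "chills"): 0.75,
    ("heart_kidney_yang_deficiency", "chills"): 0.80,
    ("cardiopulmonary_qi_deficiency", "cough"): 0.75,
    ("turbid_phlegm", "cough"): 0.30,
    ("qi_stagnation", "impetuosity_rage"): 0.50,
    ("heart_fire_hyperactivity", "impetuosity_rage"): 0.50,
    ("heart_kidney_yang_deficiency", "frequent_night_urination"): 0.80,
    ("heart_fire_hyperactivity", "like_cold_drink"): 0.60,
    ("turbid_phlegm", "cough_with_sputum"): 0.45,
    ("cardiopulmonary_qi_deficiency", "cough_with_sputum"): 0.50,
    ("heart_yang_deficiency", "cold_limbs"): 0.55,
    ("heart_kidney_yang_deficiency", "cold_limbs"): 0.45,
    ("heart_yang_deficiency", "paroxysmal_night_dyspnea"): 0.08,
    ("qi_stagnation", "lateral_thorax_distending_pain"): 0.10,
    ("heart_blood_deficiency", "constipation"): 0.50,
    ("heart_yin_deficiency", "constipation"): 0.20,
    ("cardiopulmonary_qi_deficiency", "edema"): 0.60,
    ("heart_kidney_yang_deficiency", "edema"): 0.40,
    ("turbid_phlegm", "mucosity_in_mouth"): 0.09,
    ("heart_fire_hyperactivity", "dark_urine"): 0.30,
    ("turbid_phlegm", "epigastric_upset"): 0.09,
    ("blood_stasis", "fluid_failing_resolve_thirst"): 0.04,
}


def chd_like_preset(seed: int = 0, n_cases: int = 555) -> SimulationConfig:
    """A shipped configuration shaped like a CHD inquiry-diagnosis cohort.

    555 cases, 63 symptoms with marginal frequencies spanning roughly
    0.002-0.79, and 10 co-occurring syndromes with marginals from
    ~0.025 to 0.76. Syndrome base rates and symptom background rates
    are calibrated by exact enumeration so that the model's ground-truth
    marginals hit the targets; the emission matrix plants asymmetric
    one-way patterns (e.g. paroxysmal night dyspnea -> palpitation).
    """
    syn_names = list(_SYNDROME_TARGETS)
    sym_names = list(_SYMPTOM_TARGETS)
    children = {dst for _, dst, _ in _SYNDROME_LINKS}

    # back-solve base rates of linked children so marginals hit targets
    bases: dict[str, float] = {}
    for name in syn_names:
        target = _SYNDROME_TARGETS[name]
        if name not in children:
            bases[name] = target
    for src, dst, p in _SYNDROME_LINKS:
        p_src = _SYNDROME_TARGETS[src]
        base = (_SYNDROME_TARGETS[dst] - p_src * p) / (1.0 - p_src)
        if not 0.0 <= base <= 1.0:
            raise ValueError(f"infeasible link target for {dst!r}")
        bases[dst] = base

    emissions = np.zeros((len(syn_names), len(sym_names)))
    for (syn, sym), p in _EMISSIONS.items():
        emissions[syn_names.index(syn), sym_names.index(sym)] = p

    # calibrate background rates: with eps = 0, the induced marginal is
    # 1 - A_s where A_s = E[prod_k (1 - E[k, s])]; solve eps from A_s
    probe = SimulationConfig(
        n_cases=1,
        syndromes=[(n, bases[n]) for n in syn_names],
        syndrome_links=list(_SYNDROME_LINKS),
        symptoms=[(n, 0.0) for n in sym_names],
        emissions=emissions,
        seed=0,
    )
    states, probs = _state_distribution(probe)
    floor = (probs / probs.sum()) @ _symptom_activation(probe, states)
    eps = []
    for j, name in enumerate(sym_names):
        target = _SYMPTOM_TARGETS[name]
        a = 1.0 - floor[j]
        if (1.0 - target) > a * 1.001:
            raise ValueError(
                f"emissions alone push {name!r} above its target frequency"
            )
        eps.append(max(0.0, 1.0 - (1.0 - target) / a))

    return SimulationConfig(
        n_cases=n_cases,
        syndromes=[(n, bases[n]) for n in syn_names],
        syndrome_links=list(_SYNDROME_LINKS),
        symptoms=list(zip(sym_names, eps)),
        emissions=emissions,
        seed=seed,
    )


def chd_like_targets() -> tuple[dict[str, float], dict[str, float]]:
    """The preset's target marginals: (syndromes, symptoms)."""
    return dict(_SYNDROME_TARGETS), dict(_SYMPTOM_TARGETS)
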