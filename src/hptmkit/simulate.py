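"""Synthetic peptidoform, protein and MS1-feature data with known ground truth.

The generator emulates a time-resolved stem-cell conversion design: five
passages (P0, P3, P6, P9, P12) in four biological replicates, histone H3/H4
peptide pools with planted per-residue modification trajectories, a clipping
event peaking early in the course, and an acid-extractome-like protein table
with planted cluster dynamics and structural missingness.

Generative model per peptide pool and sample: the pool total is lognormal;
within the pool, peptidoform proportions are products of independent
per-residue state probabilities (the planted RA trajectories), exactly
renormalized; each peptidoform intensity then receives independent
multiplicative lognormal replicate noise at the configured CV.  With all
noise at zero, every pipeline statistic recovers its planted value exactly.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .quantify import AbundanceMatrix, HPTMKey, format_descriptor

__all__ = [
    "BackboneSpec",
    "ClippingSpec",
    "SimulationConfig",
    "ProteinTableConfig",
    "GroundTruth",
    "default_simulation_config",
    "simulate_ra_dataset",
    "simulate_protein_table",
    "simulate_feature_list",
]

DEFAULT_PASSAGES = ("P0", "P3", "P6", "P9", "P12")
_BASE_POOL_INTENSITY = 1e6


@dataclass(frozen=True)
class BackboneSpec:
    """One peptide pool: a backbone span within a variant group.

    ``sites`` maps modifiable mature positions to their residue letter.
    ``pool_weight`` scales the pool's total intensity relative to the base.
    """

    family: str
    variant_group: str
    start: int
    end: int
    sites: tuple[tuple[int, str], ...]
    pool_weight: float = 1.0


@dataclass(frozen=True)
class ClippingSpec:
    """A clipping event: site, hosting pool, and true per-passage fraction."""

    variant_group: str
    family: str
    site: int
    end: int
    fractions: tuple[float, ...]


@dataclass
class SimulationConfig:
    """Study design, planted trajectories and noise levels.

    ``trajectories`` maps each hPTM key to its true per-passage RA.  Defaults
    (see :func:`default_simulation_config`) encode the emulated study
    conditions: n = 4 replicates per passage, 20% replicate CV, a
    K27me3-like step up at P9, an acetylation dip-and-partial-recovery, a
    transient mid-course methylation change, and an early clipping peak.
    """

    passages: tuple[str, ...] = DEFAULT_PASSAGES
    replicates: int = 4
    backbones: tuple[BackboneSpec, ...] = ()
    trajectories: dict[HPTMKey, tuple[float, ...]] = field(default_factory=dict)
    noise_cv: float = 0.20
    pool_sigma: float = 0.25
    clipping: ClippingSpec | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        for key, traj in self.trajectories.items():
            if len(traj) != len(self.passages):
                raise ValueError(f"{key.label}: trajectory length != passage count")
            if any(not 0 <= v <= 1 for v in traj):
                raise ValueError(f"{key.label}: true RA outside [0, 1]")
        # per residue, the modified states must leave room for the unmodified
        by_site: dict[tuple[str, int], np.ndarray] = {}
        for key, traj in self.trajectories.items():
            for pos in key.positions:
                site = (key.variant_group, pos)
                by_site[site] = by_site.get(site, np.zeros(len(self.passages))) + np.asarray(traj)
        for site, total in by_site.items():
            if (total > 1 + 1e-12).any():
                raise ValueError(
                    f"site {site}: modified-state RAs sum above 1 at some passage"
                )
        if self.clipping is not None and len(self.clipping.fractions) != len(self.passages):
            raise ValueError("clipping fractions length != passage count")


@dataclass
class GroundTruth:
    """Planted truth serialized alongside every generated dataset."""

    trajectories: dict[str, list[float]]
    time_varying: dict[str, bool]
    endpoint_changed: dict[str, bool]
    endpoint_direction: dict[str, str]
    clipping_fractions: list[float] | None
    pool_totals: dict[str, dict[str, float]]
    cluster_members: dict[str, list[str]] = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _h3_h4_backbones() -> tuple[BackboneSpec, ...]:
    return (
        BackboneSpec("H3", "H3", 9, 17, ((9, "K"), (14, "K")), 1.0),
        BackboneSpec("H3", "H3", 18, 26, ((18, "K"), (23, "K")), 1.0),
        BackboneSpec("H3", "H31/H32", 27, 40, ((27, "K"), (36, "K"), (37, "K")), 0.8),
        BackboneSpec("H3", "H33", 27, 40, ((27, "K"), (36, "K"), (37, "K")), 0.2),
        BackboneSpec("H4", "H4", 4, 17, ((5, "K"), (8, "K"), (12, "K"), (16, "K")), 1.0),
    )


def default_simulation_config(seed: int = 0) -> SimulationConfig:
    """The emulated study conditions with their planted trajectories.

    Planted effects: a K27me3 step from 5% to 15% RA at P9 on both H3.1/H3.2
    and (scaled) H3.3 pools; K27me2 drifting up; acetylation on K18/K23/
    H33K27/H4K12/H4K16 dipping at P3 and only partially recovering (a net
    endpoint decrease); a transient K36me2 excursion at P3 returning to
    baseline (time-significant but not a marker); slowly co-rising H4K5me
    and H4K8cr; null (constant) K9/K14 keys; clipping at K27 peaking at ~3%
    at P3.
    """
    k = HPTMKey
    trajectories: dict[HPTMKey, tuple[float, ...]] = {
        k("H31/H32", "K27", "me3"): (0.05, 0.05, 0.05, 0.15, 0.15),
        k("H31/H32", "K27", "me2"): (0.10, 0.10, 0.12, 0.14, 0.15),
        k("H33", "K27", "me3"): (0.04, 0.04, 0.04, 0.12, 0.12),
        k("H33", "K27", "ac"): (0.20, 0.08, 0.12, 0.14, 0.14),
        k("H3", "K18", "ac"): (0.25, 0.10, 0.15, 0.18, 0.18),
        k("H3", "K23", "ac"): (0.30, 0.15, 0.20, 0.24, 0.24),
        k("H3", "K9", "me3"): (0.20, 0.20, 0.20, 0.19, 0.19),
        k("H3", "K9", "ac"): (0.10, 0.10, 0.10, 0.10, 0.10),
        k("H3", "K14", "ac"): (0.15, 0.15, 0.15, 0.15, 0.15),
        k("H31/H32", "K36", "me2"): (0.10, 0.22, 0.12, 0.10, 0.10),
        k("H31/H32", "K37", "me"): (0.05, 0.05, 0.05, 0.05, 0.05),
        k("H4", "K5", "me"): (0.02, 0.02, 0.03, 0.05, 0.06),
        k("H4", "K8", "cr"): (0.02, 0.02, 0.03, 0.05, 0.06),
        k("H4", "K12", "ac"): (0.25, 0.12, 0.16, 0.18, 0.18),
        k("H4", "K16", "ac"): (0.30, 0.15, 0.20, 0.22, 0.22),
    }
    clipping = ClippingSpec(
        variant_group="H31/H32",
        family="H3",
        site=27,
        end=40,
        fractions=(0.005, 0.03, 0.01, 0.005, 0.005),
    )
    return SimulationConfig(
        backbones=_h3_h4_backbones(),
        trajectories=trajectories,
        clipping=clipping,
        seed=seed,
    )


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise at the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=size)


def simulate_ra_dataset(
    config: SimulationConfig,
) -> tuple[AbundanceMatrix, GroundTruth]:
    """Generate a peptidoform abundance table with planted RA trajectories.

    Deterministic under a fixed seed.  Raises on invalid trajectories (per
    residue, modified states must sum to at most 1 at every passage).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples = [
        f"{p}_R{r}" for p in config.passages for r in range(1, config.replicates + 1)
    ]
    passage_of = {s: s.rsplit("_R", 1)[0] for s in samples}
    n_pass = len(config.passages)
    pidx = {p: i for i, p in enumerate(config.passages)}

    rows: dict[str, np.ndarray] = {}
    pool_totals: dict[str, dict[str, float]] = {}
    for bb in config.backbones:
        site_states: list[tuple[int, str, list[tuple[str, np.ndarray]]]] = []
        for pos, letter in bb.sites:
            states: list[tuple[str, np.ndarray]] = []
            for key, traj in config.trajectories.items():
                if key.variant_group == bb.variant_group and pos in key.positions:
                    states.append((key.mod, np.asarray(traj, dtype=float)))
            unmod = 1.0 - sum(t for _, t in states) if states else np.ones(n_pass)
            states.insert(0, ("", np.asarray(unmod, dtype=float)))
            site_states.append((pos, letter, states))

        totals = bb.pool_weight * _BASE_POOL_INTENSITY * np.exp(
            rng.normal(0.0, config.pool_sigma, size=len(samples))
        ) if config.pool_sigma > 0 else np.full(
            len(samples), bb.pool_weight * _BASE_POOL_INTENSITY
        )
        pool_totals[f"{bb.variant_group} {bb.start}-{bb.end}"] = dict(
            zip(samples, totals.tolist())
        )

        for combo in itertools.product(*(states for _, _, states in site_states)):
            mods = tuple(
                (letter, pos, name)
                for (pos, letter, _), (name, _) in zip(site_states, combo)
                if name
            )
            prop = np.ones(n_pass)
            for _, traj in combo:
                prop = prop * traj
            if not (prop > 0).any():
                continue
            desc = format_descriptor(
                bb.family, bb.variant_group, bb.start, bb.end, mods
            )
            per_sample = np.array(
                [totals[i] * prop[pidx[passage_of[s]]] for i, s in enumerate(samples)]
            )
            per_sample *= _lognormal_noise(rng, config.noise_cv, len(samples))
            rows[desc] = per_sample

        if (
            config.clipping is not None
            and config.clipping.variant_group == bb.variant_group
            and bb.start <= config.clipping.site <= bb.end
        ):
            f = np.asarray(config.clipping.fractions, dtype=float)
            clip = np.array(
                [
                    totals[i] * f[pidx[passage_of[s]]] / (1 - f[pidx[passage_of[s]]])
                    for i, s in enumerate(samples)
                ]
            )
            clip *= _lognormal_noise(rng, config.noise_cv, len(samples))
            desc = format_descriptor(
                config.clipping.family,
                bb.variant_group,
                config.clipping.site + 1,
                config.clipping.end,
                (),
                clipped=True,
            )
            rows[desc] = clip

    table = pd.DataFrame(rows, index=samples).T
    matrix = AbundanceMatrix.from_wide(table, normalization_tag="synthetic")

    truth = GroundTruth(
        trajectories={k.label: list(v) for k, v in config.trajectories.items()},
        time_varying={
            k.label: bool(max(v) - min(v) > 1e-12)
            for k, v in config.trajectories.items()
        },
        endpoint_changed={
            k.label: bool(abs(v[-1] - v[0]) > 1e-12)
            for k, v in config.trajectories.items()
        },
        endpoint_direction={
            k.label: "up_in_naive"
            if v[-1] > v[0]
            else ("down_in_naive" if v[-1] < v[0] else "flat")
            for k, v in config.trajectories.items()
        },
        clipping_fractions=list(config.clipping.fractions)
        if config.clipping
        else None,
        pool_totals=pool_totals,
        seed=config.seed,
    )
    return matrix, truth


@dataclass
class ProteinTableConfig:
    """Acid-extractome-like protein table: planted dynamics and missingness.

    Defaults emulate the study scale: a 64-member translation-machinery
    cluster stepping up between P3 and P6, two macroH2A-like proteins
    spiking at P3 and then disappearing (structural missingness), one
    linker-histone-like protein detected only from P9 on, and a null
    background.
    """

    passages: tuple[str, ...] = DEFAULT_PASSAGES
    replicates: int = 4
    n_null: int = 233
    n_step: int = 64
    step_fold: float = 2.5
    transient_spike: tuple[str, ...] = ("H2AW_like", "H2AY_like")
    spike_fold: float = 3.0
    late_onset: tuple[str, ...] = ("H11_like",)
    noise_cv: float = 0.20
    base_sigma: float = 1.0
    seed: int = 0


def simulate_protein_table(
    config: ProteinTableConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a protein x sample table; missingness is encoded as NaN."""
    rng = np.random.default_rng(config.seed)
    samples = [
        f"{p}_R{r}" for p in config.passages for r in range(1, config.replicates + 1)
    ]
    passages = np.array([s.rsplit("_R", 1)[0] for s in samples])
    step_from = config.passages.index("P6") if "P6" in config.passages else 2

    names, profiles = [], []
    step_names = [f"STEP{i:03d}" for i in range(config.n_step)]
    for name in step_names:
        base = np.exp(rng.normal(np.log(1e5), config.base_sigma))
        level = np.array(
            [
                base * (config.step_fold if config.passages.index(p) >= step_from else 1.0)
                for p in passages
            ]
        )
        names.append(name)
        profiles.append(level)
    for name in config.transient_spike:
        base = np.exp(rng.normal(np.log(1e5), config.base_sigma))
        level = np.array(
            [
                base * config.spike_fold
                if p == "P3"
                else (base if p == "P0" else np.nan)
                for p in passages
            ]
        )
        names.append(name)
        profiles.append(level)
    for name in config.late_onset:
        base = np.exp(rng.normal(np.log(1e5), config.base_sigma))
        level = np.array(
            [base if p in ("P9", "P12") else np.nan for p in passages]
        )
        names.append(name)
        profiles.append(level)
    null_names = [f"NULL{i:03d}" for i in range(config.n_null)]
    for name in null_names:
        base = np.exp(rng.normal(np.log(1e5), config.base_sigma))
        names.append(name)
        profiles.append(np.full(len(samples), base))

    arr = np.vstack(profiles)
    noise = _lognormal_noise(rng, config.noise_cv, arr.shape)
    table = pd.DataFrame(arr * noise, index=names, columns=samples)

    truth = GroundTruth(
        trajectories={},
        time_varying={
            **{n: True for n in step_names},
            **{n: True for n in config.transient_spike + config.late_onset},
            **{n: False for n in null_names},
        },
        endpoint_changed={n: True for n in step_names},
        endpoint_direction={n: "up_in_naive" for n in step_names},
        clipping_fractions=None,
        pool_totals={},
        cluster_members={
            "translation_step": step_names,
            "transient_spike": list(config.transient_spike),
            "late_onset": list(config.late_onset),
            "null": null_names,
        },
        seed=config.seed,
    )
    return table, truth


def simulate_feature_list(
    peptidoforms: Sequence,
    ppm_sd: float = 3.0,
    decoy_count: int = 0,
    seed: int = 0,
) -> tuple[list[tuple[str, float]], dict[str, int]]:
    """Observed MS1 neutral masses for known peptidoforms plus mass decoys.

    Observed mass = theoretical * (1 + eps/1e6) with eps ~ Normal(0, ppm_sd);
    decoys are uniform over the observed mass range.  Returns the feature
    list and a ground-truth map feature_id -> peptidoform index (decoys map
    to -1).
    """
    if ppm_sd < 0:
        raise ValueError("ppm_sd must be >= 0")
    rng = np.random.default_rng(seed)
    features: list[tuple[str, float]] = []
    truth: dict[str, int] = {}
    masses = np.array([pf.mono_mass for pf in peptidoforms], dtype=float)
    eps = rng.normal(0.0, ppm_sd, size=len(masses)) if ppm_sd > 0 else np.zeros(len(masses))
    for i, (m, e) in enumerate(zip(masses, eps)):
        fid = f"F{i:05d}"
        features.append((fid, float(m * (1 + e * 1e-6))))
        truth[fid] = i
    if decoy_count and len(masses):
        lo, hi = masses.min(), masses.max()
        for j, m in enumerate(rng.uniform(lo, hi, size=decoy_count)):
            fid = f"D{j:05d}"
            features.append((fid, float(m)))
            truth[fid] = -1
    return features, truth
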