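"""Agent-based simulator of the group-mating experimental design.

Each replicate group holds one focal male, ``n_rivals`` rival males and
``n_females`` females, observed for ``n_days`` daily windows discretised
into ``window_slots`` mating opportunities.  After mating, a female enters a
refractory period whose duration (in slots) is geometric with mean
``refractory_mean`` — the single knob that emulates the polyandry
manipulation: a short refractory period mimics females lacking the
sex-peptide receptor (rapid return to receptivity, high polyandry), a long
one mimics wild-type controls.

Offspring are daughters only (the paternity-scorable class).  Each mated
female draws a Poisson number of daughters and sires are assigned by a
fair-raffle multinomial with tickets proportional to each male's copulation
count with her; the last male to mate optionally gets his tickets multiplied
by ``last_male_weight`` (>1 models last-male sperm precedence).

Ground truth (copulation-count matrices and expected paternity weights) is
recorded so parameter-recovery tests can compare realised against expected
quantities.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import GroupRoster, MatingEvent, PaternityRecord

#: Paired-treatment defaults.  Controls keep a long refractory period
#: (re-mating within the experiment is possible but uncommon); the
#: high-polyandry arm re-enters receptivity within a few slots and has
#: mildly reduced fecundity, mirroring the phenotype of receptor-lacking
#: females.
CONTROL_REFRACTORY = 24.0
HIGH_POLYANDRY_REFRACTORY = 3.0
HIGH_POLYANDRY_FECUNDITY_MULTIPLIER = 0.85
CONTROL_LABEL = "control"
HIGH_POLYANDRY_LABEL = "SPR-"


@dataclass
class SimConfig:
    """Generative parameters for one treatment arm.

    Defaults reproduce the study design: 29 groups of 1 focal + 3 rival
    males with 4 females over 4 daily windows, with the focal male's mating
    propensity set so he is expected to take one third of all matings
    (1.5 / (1.5 + 3) = 1/3).
    """

    n_groups: int = 29
    n_rivals: int = 3
    n_females: int = 4
    n_days: int = 4
    window_slots: int = 8
    focal_propensity: float = 1.5
    refractory_mean: float = CONTROL_REFRACTORY
    fecundity_mean: float = 12.0  # daughters per female per day
    fecundity_treatment_multiplier: float = 1.0
    last_male_weight: float = 1.0
    treatment: str = CONTROL_LABEL
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_groups", "n_rivals", "n_females", "n_days", "window_slots"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.focal_propensity < 0:
            raise ValueError("focal_propensity must be >= 0")
        if self.refractory_mean < 1:
            raise ValueError("refractory_mean must be >= 1 slot")
        if self.fecundity_mean < 0 or self.fecundity_treatment_multiplier < 0:
            raise ValueError("fecundity parameters must be >= 0")
        if self.last_male_weight < 1:
            raise ValueError("last_male_weight must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class SimTruth:
    """Ground truth recorded during simulation.

    ``copulation_counts[gid]`` is a (males × females) count matrix with the
    focal male in row 0; ``paternity_weights[gid][female]`` the multinomial
    sire weights actually used (sum to 1); ``polyandry[gid]`` the per-female
    unique-mate counts.
    """

    copulation_counts: dict[str, np.ndarray] = field(default_factory=dict)
    paternity_weights: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    polyandry: dict[str, np.ndarray] = field(default_factory=dict)
    config: SimConfig | None = None


@dataclass
class SimDataset:
    events: list[MatingEvent]
    paternity: list[PaternityRecord]
    rosters: dict[str, GroupRoster]
    truth: SimTruth


def simulate_experiment(config: SimConfig) -> SimDataset:
    """Run the group-mating simulation for one treatment arm.

    All randomness comes from a single generator seeded with
    ``config.seed``; draws occur in a fixed order (group → day → slot →
    fecundity → paternity), so identical configs give identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_males = 1 + config.n_rivals
    male_weights = np.array([config.focal_propensity] + [1.0] * config.n_rivals)
    if male_weights.sum() == 0:
        raise ValueError("at least one male must have positive mating propensity")
    male_probs = male_weights / male_weights.sum()
    p_refract = 1.0 / config.refractory_mean

    events: list[MatingEvent] = []
    paternity: list[PaternityRecord] = []
    rosters: dict[str, GroupRoster] = {}
    truth = SimTruth(config=dataclasses.replace(config))

    for g in range(config.n_groups):
        gid = f"{config.treatment}-g{g + 1:03d}"
        replicate = f"R{g % 2 + 1}"
        male_ids = [f"{gid}-M{i + 1}" for i in range(n_males)]
        female_ids = [f"{gid}-F{j + 1}" for j in range(config.n_females)]
        rosters[gid] = GroupRoster(
            group_id=gid,
            treatment=config.treatment,
            males=tuple(
                (m, "focal" if i == 0 else "rival") for i, m in enumerate(male_ids)
            ),
            females=tuple(female_ids),
            replicate_id=replicate,
        )

        counts = np.zeros((n_males, config.n_females), dtype=int)
        last_mate = np.full(config.n_females, -1, dtype=int)
        refract = np.zeros(config.n_females, dtype=int)

        for day in range(1, config.n_days + 1):
            order = 0
            for _ in range(config.window_slots):
                receptive = np.flatnonzero(refract == 0)
                if receptive.size:
                    f = int(rng.choice(receptive))
                    m = int(rng.choice(n_males, p=male_probs))
                    order += 1
                    events.append(
                        MatingEvent(
                            group_id=gid,
                            replicate_id=replicate,
                            treatment=config.treatment,
                            day=day,
                            order=order,
                            male_id=male_ids[m],
                            female_id=female_ids[f],
                        )
                    )
                    counts[m, f] += 1
                    last_mate[f] = m
                    refract[f] = int(rng.geometric(p_refract))
                refract = np.maximum(refract - 1, 0)

        weights_by_female: dict[str, np.ndarray] = {}
        fec = config.fecundity_mean * config.fecundity_treatment_multiplier
        for f in range(config.n_females):
            col = counts[:, f].astype(float)
            if col.sum() == 0:
                paternity.append(
                    PaternityRecord(gid, female_ids[f], 0, 0)
                )
                continue
            total = int(rng.poisson(fec * config.n_days))
            tickets = col.copy()
            tickets[last_mate[f]] *= config.last_male_weight
            w = tickets / tickets.sum()
            sires = rng.multinomial(total, w)
            weights_by_female[female_ids[f]] = w
            paternity.append(
                PaternityRecord(
                    gid, female_ids[f], int(sires[0]), int(total - sires[0])
                )
            )

        truth.copulation_counts[gid] = counts
        truth.paternity_weights[gid] = weights_by_female
        truth.polyandry[gid] = (counts > 0).sum(axis=0)

    return SimDataset(events=events, paternity=paternity, rosters=rosters, truth=truth)


def make_paired_treatments(base: SimConfig) -> dict[str, SimDataset]:
    """Simulate a control-like and a high-polyandry arm from one base config.

    The arms share every parameter except the refractory mean (long vs.
    short) and the fecundity multiplier (1 vs. slightly reduced).  The
    high-polyandry arm uses ``base.seed + 1`` so the two arms are
    independent yet jointly reproducible.
    """
    control = dataclasses.replace(
        base,
        treatment=CONTROL_LABEL,
        refractory_mean=CONTROL_REFRACTORY,
        fecundity_treatment_multiplier=1.0,
        seed=base.seed,
    )
    high = dataclasses.replace(
        base,
        treatment=HIGH_POLYANDRY_LABEL,
        refractory_mean=HIGH_POLYANDRY_REFRACTORY,
        fecundity_treatment_multiplier=HIGH_POLYANDRY_FECUNDITY_MULTIPLIER,
        seed=base.seed + 1,
    )
    return {
        CONTROL_LABEL: simulate_experiment(control),
        HIGH_POLYANDRY_LABEL: simulate_experiment(high),
    }


def mean_polyandry(dataset: SimDataset) -> float:
    """Mean number of unique male mates per female across all groups."""
    ks = np.concatenate(list(dataset.truth.polyandry.values()))
    return float(ks.mean())
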