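"""Seeded generators for users, pedigrees, record streams and scenarios.

Everything the other modules consume can be generated here with
controlled statistical structure: multi-generation family pedigrees with
optional monozygotic twins, per-user record streams mixing static types
(sampled at most once per user — a genome is sequenced once) with dynamic
types recurring as a Poisson process over the user's age span, and
ready-to-run marketplace scenario bundles.  All output is a pure function
of the seed; regeneration is byte-identical.

The default type registry ships five types: genome (infinite half-life),
cholesterol_panel (5-year half-life, the classic example of a test with a
stated validity horizon), blood_test (0.5 y), transcriptome (1 y) and
mri (2 y).  Base values and the latter three half-lives are plausible
fixtures chosen for the simulator, not measured quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .exceptions import ConfigError
from .pedigree import Individual, Pedigree, write_ped
from .records import (
    BiomedicalRecord,
    Dataset,
    MarketplaceParams,
    RecordTypeSpec,
    UserProfile,
    ValuationConfig,
    write_records,
)

__all__ = [
    "GeneratorSpec",
    "default_config",
    "default_config_dict",
    "gen_users",
    "gen_pedigree",
    "gen_records",
    "gen_scenario",
]

DEFAULT_TYPES: dict[str, dict] = {
    "genome": {"base_value": 10.0, "half_life": math.inf, "static": True},
    "cholesterol_panel": {"base_value": 1.0, "half_life": 5.0, "static": False},
    "blood_test": {"base_value": 0.5, "half_life": 0.5, "static": False},
    "transcriptome": {"base_value": 5.0, "half_life": 1.0, "static": False},
    "mri": {"base_value": 3.0, "half_life": 2.0, "static": False},
}

DEFAULT_SYNERGY: list[dict] = [
    {"types": ["blood_test", "transcriptome"], "value": 2.0},
    {"types": ["genome", "transcriptome"], "value": 4.0},
    {"types": ["genome", "blood_test", "transcriptome"], "value": 3.0},
]


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic population and record streams.

    Dynamic-type sampling rates are records per year of the sampled age
    span; qualities are uniform on [quality_low, quality_high] with an
    optional probability spike at exactly 0 to exercise the worthless-
    record invariance of the cost model.
    """

    n_users: int = 10
    n_families: int = 2
    generations: int = 3
    sibship_size: int = 2
    mz_twin_prob: float = 0.0
    sampling_rates: dict[str, float] = field(
        default_factory=lambda: {
            "cholesterol_panel": 0.2,
            "blood_test": 0.5,
            "transcriptome": 0.1,
            "mri": 0.05,
        }
    )
    quality_low: float = 0.5
    quality_high: float = 1.5
    zero_quality_prob: float = 0.0
    age_min: float = 20.0
    age_max: float = 70.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.sampling_rates.values()):
            raise ConfigError("sampling rates must be >= 0")
        if self.generations < 1 or self.n_families < 1 or self.sibship_size < 0:
            raise ConfigError("infeasible pedigree structure")
        if not 0 <= self.mz_twin_prob <= 1 or not 0 <= self.zero_quality_prob <= 1:
            raise ConfigError("probabilities must be in [0, 1]")


def default_config_dict() -> dict:
    """The default valuation config as a plain mapping (YAML-serializable)."""
    types = {}
    for key, body in DEFAULT_TYPES.items():
        types[key] = {
            "base_value": body["base_value"],
            "half_life": None if math.isinf(body["half_life"]) else body["half_life"],
            "display_name": key.replace("_", " "),
        }
    return {
        "types": types,
        "synergy": DEFAULT_SYNERGY,
        "group_growth": {"form": "k_log_k", "C": 1.0},
        "quality_aggregator": "reciprocal_sum",
        "max_combination_order": 4,
        "relationship_regularization": True,
        "marketplace": {
            "dv_share": 0.1,
            "validation_timeout": 10,
            "mint_on_upload": False,
            "n_keepers": 4,
            "threshold": 2,
        },
    }


def default_config(**overrides) -> ValuationConfig:
    """Build the default ValuationConfig directly (no file round-trip)."""
    registry = {
        key: RecordTypeSpec(
            type_key=key,
            base_value=body["base_value"],
            half_life=body["half_life"],
            display_name=key.replace("_", " "),
        )
        for key, body in DEFAULT_TYPES.items()
    }
    kwargs = dict(
        type_registry=registry,
        synergy_table={tuple(e["types"]): e["value"] for e in DEFAULT_SYNERGY},
        marketplace=MarketplaceParams(),
    )
    kwargs.update(overrides)
    return ValuationConfig(**kwargs)


def gen_users(spec: GeneratorSpec) -> dict[str, UserProfile]:
    """Seeded user profiles with ages uniform on [age_min, age_max]."""
    rng = np.random.default_rng(spec.seed)
    users = {}
    for i in range(spec.n_users):
        uid = f"u{i:03d}"
        users[uid] = UserProfile(
            user_id=uid,
            current_age=float(rng.uniform(spec.age_min, spec.age_max)),
            sex="male" if rng.random() < 0.5 else "female",
        )
    return users


def gen_pedigree(spec: GeneratorSpec) -> Pedigree:
    """Family pedigrees: each generation's children marry unrelated founders.

    Family f starts from one founder couple; every generation each couple
    has ``sibship_size`` children, the first of whom pairs with a fresh
    founder to form the next generation's couple.  With probability
    ``mz_twin_prob`` a sibship's first two children are monozygotic twins.
    """
    rng = np.random.default_rng(spec.seed + 1)
    individuals: list[Individual] = []
    twins: list[tuple[str, str]] = []
    for f in range(spec.n_families):
        fid = f"fam{f}"
        father, mother = f"{fid}_g0_f", f"{fid}_g0_m"
        individuals.append(Individual(father, fid, sex=1))
        individuals.append(Individual(mother, fid, sex=2))
        couple = (father, mother)
        for g in range(1, spec.generations):
            children = []
            for s in range(spec.sibship_size):
                cid = f"{fid}_g{g}_c{s}"
                sex = 1 if rng.random() < 0.5 else 2
                individuals.append(Individual(cid, fid, couple[0], couple[1], sex=sex))
                children.append(cid)
            if len(children) >= 2 and rng.random() < spec.mz_twin_prob:
                twins.append((children[0], children[1]))
            if not children:
                break
            spouse = f"{fid}_g{g}_s"
            individuals.append(Individual(spouse, fid, sex=2))
            couple = (children[0], spouse)
    return Pedigree(individuals, twins)


def gen_records(
    spec: GeneratorSpec,
    users: dict[str, UserProfile],
    config: ValuationConfig | None = None,
) -> Dataset:
    """Seeded record streams for a user population.

    Static registry types yield exactly one record per user at a uniform
    random age; each dynamic type with a positive sampling rate yields a
    Poisson(rate * age span) number of records at uniform ages over the
    span [age_min, current_age].
    """
    if not users:
        raise ConfigError("gen_records needs at least one user")
    config = config or default_config()
    rng = np.random.default_rng(spec.seed + 2)
    for t in spec.sampling_rates:
        config.spec_for(t)  # unknown type keys fail fast

    def draw_quality() -> float:
        if spec.zero_quality_prob and rng.random() < spec.zero_quality_prob:
            return 0.0
        return float(rng.uniform(spec.quality_low, spec.quality_high))

    ds = Dataset()
    counter = 0
    for uid in sorted(users):
        user = users[uid]
        for type_key in sorted(config.type_registry):
            tspec = config.type_registry[type_key]
            rate = spec.sampling_rates.get(type_key, 0.0)
            if tspec.is_static:
                ages = [float(rng.uniform(0.0, user.current_age))]
            else:
                span = max(user.current_age - spec.age_min, 0.0)
                n = int(rng.poisson(rate * span)) if rate > 0 else 0
                ages = sorted(float(rng.uniform(spec.age_min, user.current_age))
                              for _ in range(n))
            for age in ages:
                ds.add(BiomedicalRecord(
                    record_id=f"r{counter:05d}",
                    owner_id=uid,
                    type=type_key,
                    time=age,
                    quality=draw_quality(),
                ))
                counter += 1
    return ds


def gen_scenario(spec: GeneratorSpec, out_dir: str | Path):
    """Write a ready-to-run bundle: records CSV, PED (+ MZ sidecar), config YAML.

    Returns ``(scenario_config, users, dataset, pedigree)``; the files under
    ``out_dir`` reproduce the same objects through the module readers.
    """
    from .marketplace import ScenarioConfig

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    users = gen_users(spec)
    ped = gen_pedigree(spec)
    config = default_config()
    dataset = gen_records(spec, users, config)

    write_records(dataset, out_dir / "records.csv")
    write_ped(ped, out_dir / "pedigree.ped", out_dir / "pedigree.mz")
    with open(out_dir / "valuation.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(default_config_dict(), fh, sort_keys=True)

    scenario = ScenarioConfig(n_users=spec.n_users, seed=spec.seed)
    with open(out_dir / "scenario.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(vars(scenario).copy(), fh, sort_keys=True)
    return scenario, users, dataset, ped
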