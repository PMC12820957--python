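"""Synthetic cross-docking study generator with known ground truth.

Emulates the tabulated outputs a two-program docking campaign produces —
per-function score tables over two protein targets, per-program PLIP-style
interaction records, mechanistic class annotations and an experimental
pIC50 table — so every downstream consensus stage can be exercised and
validated against the generating parameters.

The statistical structure: a single latent affinity a_it per (ligand,
target) drives everything.  Scores are noisy affine reads of the latent,

    raw_j = gain_j * a_it + offset_j + target_offset_j + u_ip + eps_j,

with u_ip a noise term shared by all functions of one program for a given
ligand (inducing the within-program block correlation seen in real
campaigns) and eps_j per-function noise.  The emitted score is raw_j for
higher-is-better functions and -raw_j otherwise, so direction is pure
bookkeeping.  Docking can fail per (ligand, program) — all of that
program's functions go missing together.  True binders of a target emit
each of the target's core interaction keys per program with probability
p_core (so the two-program consensus covers a core key with probability
~ p_core**2); all ligands gain Poisson-distributed spurious contacts
outside the core.  pIC50 for binders of the designated assay target is a
noisy affine read of the same latent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    ActivityTable,
    Direction,
    InteractionRecord,
    InteractionType,
    LigandAnnotation,
    MechClass,
    ScoreTable,
    ScoringFunctionSpec,
    write_activity_table,
    write_annotations,
    write_function_specs,
    write_interaction_csv,
    write_score_table,
)

__all__ = [
    "FunctionConfig",
    "GeneratorConfig",
    "StudyBundle",
    "default_functions",
    "generate_scores",
    "generate_interactions",
    "generate_study",
    "write_study",
]

TARGETS = ("CI", "CIII")


@dataclass(frozen=True)
class FunctionConfig:
    """One simulated scoring function: identity plus its affine read of
    the latent affinity.  ``target_offset`` shifts the raw score per
    target (target-dependent behavior of real functions)."""

    name: str
    program: str
    direction: Direction
    gain: float = 1.0
    offset: float = 0.0
    noise_sd: float = 0.5
    target_offset: tuple[float, float] = (0.0, 0.0)  # (CI, CIII)

    def spec(self) -> ScoringFunctionSpec:
        return ScoringFunctionSpec(self.name, self.program, self.direction)


def default_functions() -> list[FunctionConfig]:
    """Eleven functions from two programs, mirroring a GOLD + Glide
    campaign: three higher-is-better fitness functions and eight
    energy-like lower-is-better scores, with loosely realistic offsets."""
    H, L = Direction.higher_is_better, Direction.lower_is_better
    return [
        FunctionConfig("ChemPLP Fitness", "GOLD", H, gain=4.0, offset=70.0,
                       noise_sd=2.0, target_offset=(0.0, 8.0)),
        FunctionConfig("ChemScore Fitness", "GOLD", H, gain=2.0, offset=25.0,
                       noise_sd=1.2, target_offset=(0.0, 3.0)),
        FunctionConfig("GoldScore Fitness", "GOLD", H, gain=3.5, offset=50.0,
                       noise_sd=2.0, target_offset=(0.0, -5.0)),
        FunctionConfig("MMGBSA dG Bind (GOLD)", "GOLD", L, gain=5.0, offset=45.0,
                       noise_sd=3.0, target_offset=(0.0, 4.0)),
        FunctionConfig("MBAE ASET Total Energy (GOLD)", "GOLD", L, gain=4.0,
                       offset=240.0, noise_sd=2.5, target_offset=(0.0, -10.0)),
        FunctionConfig("MBAE Del Total Energy (GOLD)", "GOLD", L, gain=4.0,
                       offset=160.0, noise_sd=2.5, target_offset=(0.0, 6.0)),
        FunctionConfig("Glide docking score", "Glide", L, gain=0.8, offset=7.5,
                       noise_sd=0.5, target_offset=(0.0, 0.5)),
        FunctionConfig("Glide IFDScore", "Glide", L, gain=2.0, offset=3168.0,
                       noise_sd=1.0, target_offset=(0.0, -40.0)),
        FunctionConfig("MMGBSA dG Bind (Glide)", "Glide", L, gain=5.0, offset=48.0,
                       noise_sd=3.0, target_offset=(0.0, -3.0)),
        FunctionConfig("MBAE ASET Total Energy (Glide)", "Glide", L, gain=4.0,
                       offset=235.0, noise_sd=2.5, target_offset=(0.0, 7.0)),
        FunctionConfig("MBAE Del Total Energy (Glide)", "Glide", L, gain=4.0,
                       offset=200.0, noise_sd=2.5, target_offset=(0.0, -5.0)),
    ]


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic generator.

    Defaults emulate the reference campaign: 28 ligands (14 CI inhibitors,
    11 CIII inhibitors, 3 uncouplers), 11 scoring functions from two
    programs, a 21-key interaction core per target, and pIC50 for the
    binders of the CIII target.
    """

    n_ci: int = 14
    n_ciii: int = 11
    n_unc: int = 3
    functions: list[FunctionConfig] = field(default_factory=default_functions)
    binder_mean: float = 2.0
    binder_sd: float = 1.0
    nonbinder_mean: float = 0.0
    nonbinder_sd: float = 1.0
    program_noise_sd: float = 0.3
    p_fail: float = 0.02
    core_size: int = 21
    p_core: float = 0.85
    p_core_nonbinder: float = 0.05
    spur_rate: float = 2.0
    act_intercept: float = 5.0
    act_slope: float = 1.0
    act_noise_sd: float = 0.3
    activity_target: str = "CIII"
    seed: int = 0

    def __post_init__(self) -> None:
        # tolerate dict-form function entries (YAML / asdict round trips)
        self.functions = [
            fc if isinstance(fc, FunctionConfig)
            else FunctionConfig(**{**fc, "direction": Direction(fc["direction"]),
                                   "target_offset": tuple(fc.get("target_offset", (0.0, 0.0)))})
            for fc in self.functions
        ]
        for name in ("binder_sd", "nonbinder_sd", "program_noise_sd",
                     "act_noise_sd", "spur_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_fail", "p_core", "p_core_nonbinder"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for fc in self.functions:
            if fc.gain <= 0:
                raise ValueError(f"gain must be > 0 for {fc.name!r}")
            if fc.noise_sd < 0:
                raise ValueError(f"noise_sd must be >= 0 for {fc.name!r}")
        if self.activity_target not in TARGETS:
            raise ValueError(f"activity_target must be one of {TARGETS}")
        if self.binder_mean <= self.nonbinder_mean:
            raise ValueError("binder latent mean must exceed nonbinder mean")

    def specs(self) -> list[ScoringFunctionSpec]:
        return [fc.spec() for fc in self.functions]

    def ligand_ids(self) -> list[str]:
        return (
            [f"CI-{i + 1:02d}" for i in range(self.n_ci)]
            + [f"CIII-{i + 1:02d}" for i in range(self.n_ciii)]
            + [f"UNC-{i + 1:02d}" for i in range(self.n_unc)]
        )

    def annotations(self) -> list[LigandAnnotation]:
        out = []
        for lig in self.ligand_ids():
            mc = (MechClass.CI_inhibitor if lig.startswith("CI-")
                  else MechClass.CIII_inhibitor if lig.startswith("CIII-")
                  else MechClass.uncoupler)
            out.append(LigandAnnotation(lig, mc))
        return out

    def binder_class(self, target: str) -> MechClass:
        return MechClass.CI_inhibitor if target == "CI" else MechClass.CIII_inhibitor


@dataclass
class StudyBundle:
    config: GeneratorConfig
    specs: list[ScoringFunctionSpec]
    score_tables: dict[str, ScoreTable]
    annotations: list[LigandAnnotation]
    interactions: dict[tuple[str, str], list[InteractionRecord]]  # (target, program)
    activities: ActivityTable
    latents: pd.DataFrame  # ligand x target


# ---------------------------------------------------------------------------


def _latents(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    ligands = cfg.ligand_ids()
    ann = {a.ligand_id: a.mech_class for a in cfg.annotations()}
    lat = pd.DataFrame(index=ligands, columns=list(TARGETS), dtype=float)
    for target in TARGETS:
        binder = cfg.binder_class(target)
        for lig in ligands:
            if ann[lig] is binder:
                mu, sd = cfg.binder_mean, cfg.binder_sd
            else:
                mu, sd = cfg.nonbinder_mean, cfg.nonbinder_sd
            lat.at[lig, target] = rng.normal(mu, sd)
    return lat


def generate_scores(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None,
    latents: pd.DataFrame | None = None,
) -> tuple[dict[str, ScoreTable], pd.DataFrame]:
    """Draw latent affinities and emit per-target score tables.

    Failures are drawn per (ligand, program): when a program's run fails
    for a ligand at a target, every score that program produced goes
    missing together.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if latents is None:
        latents = _latents(cfg, rng)
    ligands = cfg.ligand_ids()
    programs = sorted({fc.program for fc in cfg.functions})
    tables: dict[str, ScoreTable] = {}
    for t_idx, target in enumerate(TARGETS):
        # shared per-(ligand, program) noise and joint failure flags
        u = {(lig, p): rng.normal(0.0, cfg.program_noise_sd)
             for lig in ligands for p in programs}
        fail = {(lig, p): rng.random() < cfg.p_fail
                for lig in ligands for p in programs}
        df = pd.DataFrame(index=pd.Index(ligands, name="ligand_id"), dtype=float)
        for fc in cfg.functions:
            col = []
            for lig in ligands:
                if fail[(lig, fc.program)]:
                    col.append(np.nan)
                    continue
                raw = (fc.gain * latents.at[lig, target] + fc.offset
                       + fc.target_offset[t_idx] + u[(lig, fc.program)]
                       + rng.normal(0.0, fc.noise_sd))
                col.append(raw if fc.direction is Direction.higher_is_better else -raw)
            df[fc.name] = col
        tables[target] = ScoreTable(target_id=target, scores=df)
    return tables, latents


_CORE_CHAINS = {"CI": ("C", "Q"), "CIII": ("C",)}
_ITYPES = list(InteractionType)


def _core_keys(cfg: GeneratorConfig, target: str) -> list[tuple[str, int, str, str]]:
    """Deterministic per-target core interaction keys, disjoint across
    targets (residue numbering blocks do not overlap)."""
    base = 100 if target == "CI" else 300
    chains = _CORE_CHAINS[target]
    restypes = ["PHE", "LEU", "VAL", "TYR", "ALA", "MET", "ILE", "GLU", "HIS", "SER"]
    keys = []
    for i in range(cfg.core_size):
        itype = _ITYPES[i % 3]  # hydrophobic, h-bond, pi-stack dominate PLIP output
        keys.append(
            (itype.value, base + i, restypes[i % len(restypes)], chains[i % len(chains)])
        )
    return keys


def _spur_pool(target: str, program_idx: int) -> list[tuple[str, int, str, str]]:
    """Spurious-contact pool, disjoint from every core and between the two
    programs: spurious contacts are placement-algorithm artifacts and must
    never survive the cross-program consensus."""
    base = (200 if target == "CI" else 400) + 50 * program_idx
    chains = _CORE_CHAINS[target]
    restypes = ["GLY", "THR", "ASN", "ASP", "LYS", "ARG", "TRP", "PRO"]
    return [
        (_ITYPES[i % len(_ITYPES)].value, base + i, restypes[i % len(restypes)],
         chains[i % len(chains)])
        for i in range(40)
    ]


def generate_interactions(
    cfg: GeneratorConfig,
    latents: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> dict[tuple[str, str], list[InteractionRecord]]:
    """Emit per-(target, program) interaction records.

    True binders of a target emit each core key independently per program
    with probability ``p_core``; nonbinders with ``p_core_nonbinder``.
    Every ligand additionally gains Poisson(``spur_rate``) spurious keys
    per program, drawn from program-specific pools outside the core, so
    the two-program consensus removes them entirely and a binder's
    consensus size is Binomial(core_size, p_core**2).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    ann = {a.ligand_id: a.mech_class for a in cfg.annotations()}
    programs = sorted({fc.program for fc in cfg.functions})
    out: dict[tuple[str, str], list[InteractionRecord]] = {}
    for target in TARGETS:
        core = _core_keys(cfg, target)
        binder = cfg.binder_class(target)
        for p_idx, program in enumerate(programs):
            pool = _spur_pool(target, p_idx)
            recs: list[InteractionRecord] = []
            for lig in cfg.ligand_ids():
                p = cfg.p_core if ann[lig] is binder else cfg.p_core_nonbinder
                for key in core:
                    if rng.random() < p:
                        recs.append(InteractionRecord(
                            interaction_type=InteractionType(key[0]),
                            residue_number=key[1], residue_type=key[2],
                            chain=key[3], ligand_id=lig, program=program))
                n_spur = rng.poisson(cfg.spur_rate)
                if n_spur > 0:
                    for idx in rng.choice(len(pool), size=min(n_spur, len(pool)),
                                          replace=False):
                        key = pool[idx]
                        recs.append(InteractionRecord(
                            interaction_type=InteractionType(key[0]),
                            residue_number=key[1], residue_type=key[2],
                            chain=key[3], ligand_id=lig, program=program))
            out[(target, program)] = recs
    return out


def generate_study(cfg: GeneratorConfig) -> StudyBundle:
    """Compose scores, interactions and activities into a full study with
    ground truth.  Fully determined by the config (including its seed)."""
    rng = np.random.default_rng(cfg.seed)
    tables, latents = generate_scores(cfg, rng)
    interactions = generate_interactions(cfg, latents, rng)
    binder = cfg.binder_class(cfg.activity_target)
    pic50: dict[str, float] = {}
    sd: dict[str, float] = {}
    for a in cfg.annotations():
        if a.mech_class is binder:
            val = (cfg.act_intercept
                   + cfg.act_slope * latents.at[a.ligand_id, cfg.activity_target]
                   + rng.normal(0.0, cfg.act_noise_sd))
            pic50[a.ligand_id] = float(val)
            sd[a.ligand_id] = cfg.act_noise_sd
    return StudyBundle(
        config=cfg,
        specs=cfg.specs(),
        score_tables=tables,
        annotations=cfg.annotations(),
        interactions=interactions,
        activities=ActivityTable(pic50=pic50, sd=sd),
        latents=latents,
    )


def write_study(bundle: StudyBundle, outdir: str | Path) -> list[Path]:
    """Serialize a bundle in the standard I/O formats so the full pipeline
    runs on synthetic output unchanged.  Returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    p = outdir / "functions.csv"
    write_function_specs(bundle.specs, p)
    written.append(p)
    p = outdir / "annotations.csv"
    write_annotations(bundle.annotations, p)
    written.append(p)
    for target, table in bundle.score_tables.items():
        p = outdir / f"scores_{target}.csv"
        write_score_table(table, p)
        written.append(p)
    for (target, program), recs in bundle.interactions.items():
        p = outdir / f"interactions_{target}_{program}.csv"
        write_interaction_csv(recs, p)
        written.append(p)
    p = outdir / "activities.csv"
    write_activity_table(bundle.activities, p)
    written.append(p)
    p = outdir / "latents.csv"
    bundle.latents.rename_axis("ligand_id").to_csv(p)
    written.append(p)
    return written
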