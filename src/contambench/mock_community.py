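"""Ground-truth mock communities and truth-labelled count simulation.

The simulator emulates a sequins-style synthetic spike-in community: a pool
of artificial DNA sequences combined on a twofold molar ladder across
staggered concentration tiers, serially diluted to sub-nanogram inputs and
converted to libraries with one of five low-input kits.  Each simulated
library is a genus/component-level read-count table in which every row is
truth-labelled as designated signal (``sequins``), reagent contamination
introduced by the kit (``kit_contaminant``), or template-borne contamination
that scales with input (``endogenous_contaminant``).

Reads sample *mass*: the expected read share of the sequins block is
``input / (input + drawn contaminant mass)``, and within the sequins block
each component's share is its mass fraction modulated by an exponential
GC/length bias term.  Counts are drawn once from a single multinomial at the
configured depth, so the spike-in ratio estimator downstream is unbiased by
construction.  Library complexity is modelled by resampling reads from a
finite pool of unique molecules, which yields kit- and input-dependent
duplication rates without fragment-level simulation.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KITS",
    "DEFAULT_LOAD_MEDIANS_PG",
    "DILUTION_SERIES_PG",
    "GC_RANGE",
    "LENGTH_RANGE_BP",
    "SEQUINS_LABEL",
    "KIT_CONTAMINANT_LABEL",
    "ENDOGENOUS_LABEL",
    "CONTAMINANT_LABELS",
    "InvalidDesignError",
    "InvalidConfigError",
    "Component",
    "CommunityDesign",
    "ContaminantGenus",
    "ContaminantPool",
    "EndogenousModel",
    "BiasModel",
    "LibraryConfig",
    "ReadCountProfile",
    "build_design",
    "default_pools",
    "default_bias",
    "simulate_library",
    "simulate_experiment",
    "derive_seed",
]

KITS = ("Son_N", "Son_Q", "End_N", "End_Q", "Tn5_V")

#: Median mass (pg) of kit-introduced contaminating DNA per library.
DEFAULT_LOAD_MEDIANS_PG = {
    "Son_Q": 15.59,
    "Son_N": 2.32,
    "End_N": 0.05,
    "End_Q": 0.04,
    "Tn5_V": 0.01,
}

DILUTION_SERIES_PG = (5000.0, 500.0, 50.0, 5.0, 0.5)
GC_RANGE = (0.294, 0.7106)
LENGTH_RANGE_BP = (1929, 9120)

SEQUINS_LABEL = "sequins"
KIT_CONTAMINANT_LABEL = "kit_contaminant"
ENDOGENOUS_LABEL = "endogenous_contaminant"
CONTAMINANT_LABELS = (KIT_CONTAMINANT_LABEL, ENDOGENOUS_LABEL)

#: Fraction of input molecules recovered into sequenceable library, per kit.
#: Ordering mirrors the observed conversion-rate ranking
#: (endonuclease > tagmentation > sonication).
KIT_RECOVERY = {
    "End_N": 0.15,
    "End_Q": 0.12,
    "Tn5_V": 0.08,
    "Son_N": 0.01,
    "Son_Q": 0.005,
}

DEFAULT_PCR_CYCLES = {
    "Son_N": 15,
    "Son_Q": 16,
    "End_N": 12,
    "End_Q": 12,
    "Tn5_V": 13,
}

# Average double-stranded base-pair mass, g/mol.
_BP_G_PER_MOL = 650.0
_AVOGADRO = 6.02214076e23

#: Contaminant genera found in every kit's reagent pool (a scaled-down core
#: set of genera commonly reported as reagent contaminants).
SHARED_CONTAMINANT_GENERA = (
    "Acinetobacter", "Bradyrhizobium", "Methylobacterium", "Cutibacterium",
    "Staphylococcus", "Corynebacterium", "Streptococcus", "Klebsiella",
    "Pseudomonas", "Ralstonia", "Sphingomonas", "Burkholderia",
    "Delftia", "Stenotrophomonas", "Comamonas", "Variovorax",
    "Herbaspirillum", "Aquabacterium", "Micrococcus", "Bacillus",
    "Paracoccus", "Novosphingobium", "Mesorhizobium", "Rhodococcus",
    "Deinococcus", "Flavobacterium", "Chryseobacterium",
    "Janthinobacterium", "Massilia", "Caulobacter",
)

#: Kit-unique contaminant genera (counts follow the qualitative per-kit
#: uniqueness ranking: End_Q most, then Son_N, Tn5_V, End_N; Son_Q none).
UNIQUE_CONTAMINANT_GENERA = {
    "End_Q": ("Geobacillus", "Thermus", "Anoxybacillus", "Brevundimonas",
              "Curvibacter", "Pelomonas"),
    "Son_N": ("Leifsonia", "Dietzia", "Kocuria", "Roseomonas"),
    "Tn5_V": ("Paenibacillus", "Lysinibacillus", "Acidovorax"),
    "End_N": ("Undibacterium", "Duganella"),
    "Son_Q": (),
}

#: Genera residing in the template material itself; their mass scales with
#: the input amount rather than with the kit.
ENDOGENOUS_GENERA = (
    "Escherichia", "Gammaretrovirus", "Citrobacter", "Mastadenovirus",
    "Shigella",
)


class InvalidDesignError(ValueError):
    """A community design violates its structural invariants."""


class InvalidConfigError(ValueError):
    """A simulation configuration is unusable."""


@dataclass(frozen=True)
class Component:
    """One synthetic community member."""

    id: str
    length_bp: int
    gc: float
    tier: int
    molar_level: float
    mass_fraction: float


@dataclass
class CommunityDesign:
    """Ground-truth community: components on a twofold molar tier ladder."""

    components: list[Component]
    n_tiers: int

    def validate(self) -> None:
        if not self.components:
            raise InvalidDesignError("design has no components")
        tiers = sorted({c.tier for c in self.components})
        if tiers != list(range(1, self.n_tiers + 1)):
            raise InvalidDesignError(
                f"expected tiers 1..{self.n_tiers}, found {tiers}")
        for t in tiers:
            n = sum(c.tier == t for c in self.components)
            if n < 5:
                raise InvalidDesignError(f"tier {t} has only {n} components")
        mf = [c.mass_fraction for c in self.components]
        if abs(sum(mf) - 1.0) > 1e-9:
            raise InvalidDesignError("mass fractions do not sum to 1")
        if any(f <= 0 for f in mf):
            raise InvalidDesignError("non-positive mass fraction")
        molar = [c.molar_level for c in self.components]
        if max(molar) / min(molar) != 2.0 ** (self.n_tiers - 1):
            raise InvalidDesignError("molar ladder is not an exact twofold series")
        for c in self.components:
            if not (LENGTH_RANGE_BP[0] <= c.length_bp <= LENGTH_RANGE_BP[1]):
                raise InvalidDesignError(f"{c.id}: length {c.length_bp} out of range")
            if not (GC_RANGE[0] <= c.gc <= GC_RANGE[1]):
                raise InvalidDesignError(f"{c.id}: GC {c.gc} out of range")
        ids = [c.id for c in self.components]
        if len(set(ids)) != len(ids):
            raise InvalidDesignError("duplicate component ids")

    @property
    def mass_fractions(self) -> dict[str, float]:
        return {c.id: c.mass_fraction for c in self.components}

    @property
    def gc_by_id(self) -> dict[str, float]:
        return {c.id: c.gc for c in self.components}

    @property
    def length_by_id(self) -> dict[str, int]:
        return {c.id: c.length_bp for c in self.components}

    def mass_weighted_mean_gc(self) -> float:
        return float(sum(c.mass_fraction * c.gc for c in self.components))

    def to_dict(self) -> dict:
        return {
            "n_tiers": self.n_tiers,
            "components": [vars(c) for c in self.components],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CommunityDesign":
        comps = [Component(**c) for c in d["components"]]
        design = cls(components=comps, n_tiers=int(d["n_tiers"]))
        design.validate()
        return design


def build_design(n_components: int = 83, n_tiers: int = 8,
                 seed: int = 0) -> CommunityDesign:
    """Generate a community design on a twofold molar ladder.

    Components are assigned to tiers so every tier holds at least five of
    them; GC contents and lengths are drawn uniformly over the community's
    stated ranges, and mass fractions are proportional to
    ``molar_level * length_bp`` (reads sample bases, not molecules).
    """
    if n_tiers < 2:
        raise InvalidDesignError("need at least 2 tiers")
    if n_components < 5 * n_tiers:
        raise InvalidDesignError(
            f"{n_components} components cannot cover {n_tiers} tiers "
            "with >=5 components each")
    rng = np.random.default_rng(seed)
    counts = np.full(n_tiers, 5, dtype=int)
    extra = n_components - 5 * n_tiers
    if extra:
        counts += np.bincount(rng.integers(0, n_tiers, size=extra),
                              minlength=n_tiers)
    tiers = np.repeat(np.arange(1, n_tiers + 1), counts)
    gc = rng.uniform(GC_RANGE[0], GC_RANGE[1], size=n_components)
    lengths = rng.integers(LENGTH_RANGE_BP[0], LENGTH_RANGE_BP[1] + 1,
                           size=n_components)
    molar = 2.0 ** (tiers - 1)
    weights = molar * lengths
    mass_fractions = weights / weights.sum()
    components = [
        Component(
            id=f"SQ{i + 1:03d}",
            length_bp=int(lengths[i]),
            gc=float(gc[i]),
            tier=int(tiers[i]),
            molar_level=float(molar[i]),
            mass_fraction=float(mass_fractions[i]),
        )
        for i in range(n_components)
    ]
    design = CommunityDesign(components=components, n_tiers=n_tiers)
    design.validate()
    return design


@dataclass(frozen=True)
class ContaminantGenus:
    genus: str
    shared: bool
    log_mean: float
    log_sigma: float


@dataclass
class ContaminantPool:
    """Kit-specific reagent contaminant pool.

    ``load_median_pg`` is the median total contaminating DNA mass drawn per
    library; ``load_dispersion`` is the natural-log sigma of the
    median-preserving lognormal the load is drawn from.  Per-genus lognormal
    parameters shape the kit's characteristic contaminant composition.
    """

    kit: str
    genera: list[ContaminantGenus]
    load_median_pg: float
    load_dispersion: float

    def validate(self) -> None:
        if self.load_median_pg < 0:
            raise InvalidConfigError("negative contaminant load median")
        if self.load_dispersion < 0:
            raise InvalidConfigError("negative load dispersion")
        names = [g.genus for g in self.genera]
        if len(set(names)) != len(names):
            raise InvalidConfigError("duplicate genus in pool")

    @property
    def shared_genera(self) -> set[str]:
        return {g.genus for g in self.genera if g.shared}

    def to_dict(self) -> dict:
        return {
            "kit": self.kit,
            "load_median_pg": self.load_median_pg,
            "load_dispersion": self.load_dispersion,
            "genera": [vars(g) for g in self.genera],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ContaminantPool":
        pool = cls(
            kit=d["kit"],
            genera=[ContaminantGenus(**g) for g in d["genera"]],
            load_median_pg=float(d["load_median_pg"]),
            load_dispersion=float(d["load_dispersion"]),
        )
        pool.validate()
        return pool


def default_pools(seed: int = 0,
                  load_medians: Mapping[str, float] | None = None,
                  load_dispersion: float = 1.0,
                  genus_sigma: float = 0.6,
                  profile_sigma: float = 1.5,
                  kits: Sequence[str] = KITS) -> dict[str, ContaminantPool]:
    """Build the five kit contaminant pools.

    The shared genus set is identical across kits, but each kit draws its
    own per-genus abundance centres (``profile_sigma`` controls their
    spread), so contaminant composition is kit-specific while individual
    libraries vary around it with per-library sigma ``genus_sigma``.
    """
    medians = dict(DEFAULT_LOAD_MEDIANS_PG)
    if load_medians:
        medians.update(load_medians)
    pools: dict[str, ContaminantPool] = {}
    for kit in kits:
        rng = np.random.default_rng(derive_seed(seed, f"pool:{kit}"))
        genera = [
            ContaminantGenus(genus=g, shared=True,
                             log_mean=float(rng.normal(0.0, profile_sigma)),
                             log_sigma=genus_sigma)
            for g in SHARED_CONTAMINANT_GENERA
        ]
        genera += [
            ContaminantGenus(genus=g, shared=False,
                             log_mean=float(rng.normal(0.0, profile_sigma)),
                             log_sigma=genus_sigma)
            for g in UNIQUE_CONTAMINANT_GENERA.get(kit, ())
        ]
        pool = ContaminantPool(kit=kit, genera=genera,
                               load_median_pg=float(medians[kit]),
                               load_dispersion=float(load_dispersion))
        pool.validate()
        pools[kit] = pool
    return pools


@dataclass
class EndogenousModel:
    """Template-borne contaminants whose mass is a fixed fraction of input."""

    genera: tuple[str, ...] = ENDOGENOUS_GENERA
    weights: tuple[float, ...] = (0.35, 0.25, 0.18, 0.12, 0.10)
    mass_fraction_of_input: float = 0.001
    jitter_sigma: float = 0.3


DEFAULT_ENDOGENOUS = EndogenousModel()


@dataclass
class BiasModel:
    """Log-linear enrichment bias in GC (deviation from 0.5) and length (kb).

    All-zero coefficients give unbiased mass-proportional sampling.  The WGA
    coefficients are added on top of the kit coefficients when a library is
    whole-genome amplified (longer fragments enriched, low-GC favoured).
    """

    gc_coefficient: float = 0.0
    length_coefficient: float = 0.0
    wga_length_coefficient: float = 0.0
    wga_gc_coefficient: float = 0.0

    def validate(self) -> None:
        for name, v in vars(self).items():
            if not math.isfinite(v):
                raise InvalidConfigError(f"bias coefficient {name} not finite")


def default_bias() -> BiasModel:
    """Kit-level defaults: weak positive length bias, low-GC shift; WGA adds
    a stronger length preference and a stronger low-GC preference."""
    return BiasModel(gc_coefficient=-0.8, length_coefficient=0.05,
                     wga_length_coefficient=0.3, wga_gc_coefficient=-3.0)


@dataclass
class LibraryConfig:
    """One simulated library (input mass 0 = negative control)."""

    library_id: str
    kit: str
    input_mass_pg: float
    replicate: int
    depth: int
    seed: int
    wga: bool = False
    n_pcr_cycles: int | None = None

    def validate(self) -> None:
        if self.depth <= 0:
            raise InvalidConfigError("depth must be positive")
        if self.input_mass_pg < 0:
            raise InvalidConfigError("negative input mass")

    @property
    def is_negative_control(self) -> bool:
        return self.input_mass_pg == 0


@dataclass
class ReadCountProfile:
    """Taxon-by-read-count table with provenance labels for one library.

    ``counts`` has columns ``taxon``, ``label``, ``reads``; the label is one
    of ``sequins``, ``kit_contaminant``, ``endogenous_contaminant``.  ``meta``
    carries simulator bookkeeping (planted masses, molecule counts, library
    yield) used by metrics and parameter-recovery checks.
    """

    library_id: str
    kit: str
    input_pg: float
    replicate: int
    counts: pd.DataFrame
    total_depth: int
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        expected = {"taxon", "label", "reads"}
        if not expected.issubset(self.counts.columns):
            raise ValueError(f"profile table missing columns {expected}")
        if (self.counts["reads"] < 0).any():
            raise ValueError("negative read count")
        if int(self.counts["reads"].sum()) != self.total_depth:
            raise ValueError("read counts do not sum to total depth")
        if self.counts["taxon"].duplicated().any():
            raise ValueError("duplicate taxon in profile")

    def label_reads(self, labels: Sequence[str]) -> int:
        sel = self.counts["label"].isin(labels)
        return int(self.counts.loc[sel, "reads"].sum())

    @property
    def sequins_reads(self) -> int:
        return self.label_reads([SEQUINS_LABEL])

    @property
    def contaminant_reads(self) -> int:
        return self.label_reads(CONTAMINANT_LABELS)

    def drop_taxa(self, taxa: set[str]) -> "ReadCountProfile":
        """Return a copy without the given taxa (depth re-totalled)."""
        kept = self.counts[~self.counts["taxon"].isin(taxa)].reset_index(drop=True)
        return replace(self, counts=kept, total_depth=int(kept["reads"].sum()),
                       meta=dict(self.meta))


def derive_seed(master_seed: int, name: str) -> int:
    """Stable per-stream seed below 2**31 from a master seed and a label."""
    digest = hashlib.blake2b(f"{master_seed}:{name}".encode(),
                             digest_size=4).digest()
    return int.from_bytes(digest, "big") & 0x7FFFFFFF


def _molecules_per_pg(length_bp: float) -> float:
    return 1e-12 * _AVOGADRO / (_BP_G_PER_MOL * length_bp)


def simulate_library(design: CommunityDesign,
                     config: LibraryConfig,
                     pool: ContaminantPool,
                     bias: BiasModel | None = None,
                     endo: EndogenousModel | None = None) -> ReadCountProfile:
    """Simulate one truth-labelled count profile.

    The sequins/contaminant read split is mass-proportional and unbiased;
    GC/length bias only redistributes reads *within* the sequins block, so
    the spike-in mass-ratio estimator remains exact in expectation.
    """
    config.validate()
    if pool.kit != config.kit:
        raise InvalidConfigError(
            f"pool kit {pool.kit} does not match library kit {config.kit}")
    bias = bias or BiasModel()
    bias.validate()
    endo = endo if endo is not None else DEFAULT_ENDOGENOUS
    rng = np.random.default_rng(config.seed)
    input_mass = config.input_mass_pg

    # Kit contaminant load: median-preserving lognormal.
    if pool.load_median_pg > 0:
        load = pool.load_median_pg * math.exp(
            pool.load_dispersion * rng.standard_normal())
    else:
        load = 0.0
        rng.standard_normal()  # keep stream alignment across load settings

    taxa: list[str] = []
    labels: list[str] = []
    masses: list[float] = []

    # Sequins block: total mass = input; bias redistributes within.
    gc_coef = bias.gc_coefficient + (bias.wga_gc_coefficient if config.wga else 0.0)
    len_coef = bias.length_coefficient + (
        bias.wga_length_coefficient if config.wga else 0.0)
    if input_mass > 0:
        mf = np.array([c.mass_fraction for c in design.components])
        gc = np.array([c.gc for c in design.components])
        length_kb = np.array([c.length_bp for c in design.components]) / 1000.0
        w = mf * np.exp(gc_coef * (gc - 0.5) + len_coef * length_kb)
        seq_mass = w / w.sum() * input_mass
        taxa += [c.id for c in design.components]
        labels += [SEQUINS_LABEL] * len(design.components)
        masses += list(seq_mass)

    # Kit contaminants: genus shares drawn around kit-specific centres.
    if pool.genera:
        z = rng.normal(size=len(pool.genera))
        w = np.exp(np.array([g.log_mean for g in pool.genera])
                   + np.array([g.log_sigma for g in pool.genera]) * z)
        kit_mass = w / w.sum() * load
        taxa += [g.genus for g in pool.genera]
        labels += [KIT_CONTAMINANT_LABEL] * len(pool.genera)
        masses += list(kit_mass)

    # Endogenous contaminants: mass proportional to input.
    endo_mass_total = endo.mass_fraction_of_input * input_mass
    if endo.genera:
        jitter = np.exp(endo.jitter_sigma * rng.normal(size=len(endo.genera)))
        w = np.array(endo.weights) * jitter
        endo_mass = w / w.sum() * endo_mass_total
        taxa += list(endo.genera)
        labels += [ENDOGENOUS_LABEL] * len(endo.genera)
        masses += list(endo_mass)

    mass_arr = np.asarray(masses, dtype=float)
    total_mass = float(mass_arr.sum())
    if total_mass <= 0:
        raise InvalidConfigError(
            f"{config.library_id}: no DNA mass to sequence "
            "(zero input and zero contaminant load)")
    counts = rng.multinomial(config.depth, mass_arr / total_mass)

    # Finite-molecule duplication bookkeeping.
    kit_recovery = KIT_RECOVERY.get(config.kit, 0.05)
    mean_len = float(np.mean([c.length_bp for c in design.components]))
    n_molecules = max(1, int(round(
        total_mass * _molecules_per_pg(mean_len) * kit_recovery)))
    molecule_ids = rng.integers(0, n_molecules, size=config.depth)
    n_unique = int(np.unique(molecule_ids).size)

    n_pcr = config.n_pcr_cycles or DEFAULT_PCR_CYCLES.get(config.kit, 12)
    yield_noise = math.exp(0.15 * rng.standard_normal())
    library_yield_pg = total_mass * kit_recovery * (2.0 ** n_pcr) * yield_noise

    table = pd.DataFrame({
        "taxon": taxa,
        "label": labels,
        "reads": counts.astype(int),
    })
    profile = ReadCountProfile(
        library_id=config.library_id,
        kit=config.kit,
        input_pg=input_mass,
        replicate=config.replicate,
        counts=table,
        total_depth=int(config.depth),
        meta={
            "kit_contaminant_mass_pg": float(load),
            "endogenous_mass_pg": float(endo_mass_total),
            "total_mass_pg": total_mass,
            "n_molecules": n_molecules,
            "n_unique_molecules": n_unique,
            "library_yield_pg": float(library_yield_pg),
            "n_pcr_cycles": int(n_pcr),
            "wga": bool(config.wga),
            "seed": int(config.seed),
        },
    )
    profile.validate()
    return profile


def _format_input(input_pg: float) -> str:
    return f"{input_pg:g}"


def simulate_experiment(design: CommunityDesign,
                        kits: Sequence[str],
                        dilution_series: Sequence[float] = DILUTION_SERIES_PG,
                        replicates: int = 2,
                        pools: Mapping[str, ContaminantPool] | None = None,
                        bias: BiasModel | None = None,
                        seed: int = 0,
                        depth: int = 100_000,
                        n_nc: int = 2,
                        endo: EndogenousModel | None = None,
                        wga: bool = False) -> list[ReadCountProfile]:
    """Simulate a full dilution-series experiment.

    Yields one profile per (kit, input, replicate) plus ``n_nc`` negative
    controls per kit.  Each library runs on its own RNG stream seeded from
    ``(seed, library_id)``, so the experiment is reproducible and individual
    libraries can be re-simulated in isolation.
    """
    if not kits:
        raise InvalidConfigError("kit list is empty")
    if not dilution_series:
        raise InvalidConfigError("dilution series is empty")
    if n_nc < 2:
        raise InvalidConfigError("need at least 2 negative controls per kit")
    pools = pools or default_pools(seed=seed, kits=kits)
    profiles: list[ReadCountProfile] = []
    for kit in kits:
        if kit not in pools:
            raise InvalidConfigError(f"no contaminant pool for kit {kit}")
        for input_pg in dilution_series:
            for rep in range(1, replicates + 1):
                lib_id = f"{kit}_{_format_input(input_pg)}pg_rep{rep}"
                cfg = LibraryConfig(
                    library_id=lib_id, kit=kit, input_mass_pg=float(input_pg),
                    replicate=rep, depth=depth, wga=wga,
                    seed=derive_seed(seed, lib_id))
                profiles.append(simulate_library(design, cfg, pools[kit],
                                                 bias=bias, endo=endo))
        for j in range(1, n_nc + 1):
            lib_id = f"{kit}_NC{j}"
            cfg = LibraryConfig(
                library_id=lib_id, kit=kit, input_mass_pg=0.0,
                replicate=j, depth=depth, wga=wga,
                seed=derive_seed(seed, lib_id))
            profiles.append(simulate_library(design, cfg, pools[kit],
                                             bias=bias, endo=endo))
    return profiles
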