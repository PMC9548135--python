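"""Absolute contaminant quantification and contaminant characterization.

The synthetic community doubles as an internal spike-in scale: because reads
sample mass identically for designated and contaminating DNA, the absolute
contaminant mass in a library is the input mass times the contaminant-to-
sequins read ratio.  This module also screens for endogenous (template-borne)
contaminants whose abundance tracks the input amount, builds per-kit
core/dominant contaminant catalogs, and computes the remaining-contaminant
curve under abundance filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mock_community import (
    CONTAMINANT_LABELS,
    SEQUINS_LABEL,
    ReadCountProfile,
)

__all__ = [
    "NotQuantifiableError",
    "ContaminantMassEstimate",
    "quantify_contaminant_mass",
    "EndogenousFlag",
    "detect_endogenous",
    "ContaminantCatalog",
    "core_contaminants",
    "dominant_contaminants",
    "remaining_fraction_curve",
]


class NotQuantifiableError(ValueError):
    """Spike-in quantification is impossible (no designated reads)."""


@dataclass
class ContaminantMassEstimate:
    library_id: str
    mass_pg: float


def quantify_contaminant_mass(profile: ReadCountProfile,
                              input_mass_pg: float | None = None,
                              labels: Sequence[str] = CONTAMINANT_LABELS,
                              ) -> ContaminantMassEstimate:
    """Estimate absolute contaminant mass via the spike-in read ratio.

    ``mass = input * contaminant_reads / sequins_reads``; valid only when
    the library contains designated reads (negative controls do not).
    """
    input_mass = profile.input_pg if input_mass_pg is None else input_mass_pg
    if input_mass <= 0:
        raise NotQuantifiableError(
            f"{profile.library_id}: input mass must be positive")
    seq_reads = profile.sequins_reads
    if seq_reads <= 0:
        raise NotQuantifiableError(
            f"{profile.library_id}: no designated reads to anchor the "
            "spike-in ratio")
    contam_reads = profile.label_reads(labels)
    return ContaminantMassEstimate(
        library_id=profile.library_id,
        mass_pg=input_mass * contam_reads / seq_reads)


@dataclass
class EndogenousFlag:
    """Per-genus outcome of the endogenous-contaminant screen."""

    genus: str
    per_kit: dict[str, dict] = field(default_factory=dict)
    n_kits_significant: int = 0
    flagged: bool = False


def _contaminant_abundances(profile: ReadCountProfile) -> dict[str, float] | None:
    """Contaminant-normalized genus abundances, or None if no contaminant
    reads."""
    table = profile.counts[profile.counts["label"].isin(CONTAMINANT_LABELS)]
    total = table["reads"].sum()
    if total <= 0:
        return None
    return {t: r / total for t, r in zip(table["taxon"], table["reads"])}


def detect_endogenous(profiles: Sequence[ReadCountProfile],
                      alpha: float = 0.05,
                      r2_min: float = 0.55,
                      min_kits: int = 4,
                      log_input: bool = True) -> list[EndogenousFlag]:
    """Screen for genera whose contaminant-normalized abundance rises with
    the input amount.

    Per kit, each genus's abundance (normalized to total contaminating
    reads) is regressed on log10 input mass (the dilution ladder is
    geometric; ``log_input=False`` uses the raw mass); p-values are BH-
    corrected within kit.  A genus is flagged when it shows a positive slope
    with ``p_adj < alpha`` and ``R^2 > r2_min`` in at least ``min_kits``
    kits.
    """
    positives = [p for p in profiles if p.input_pg > 0]
    by_kit: dict[str, list[ReadCountProfile]] = {}
    for p in positives:
        by_kit.setdefault(p.kit, []).append(p)
    if len(by_kit) < 2:
        raise ValueError("need libraries from at least 2 kits")
    for kit, libs in by_kit.items():
        if len({p.input_pg for p in libs}) < 3:
            raise ValueError(f"kit {kit}: need >=3 distinct input levels")

    results: dict[str, EndogenousFlag] = {}
    for kit, libs in sorted(by_kit.items()):
        rows = []
        for p in libs:
            ab = _contaminant_abundances(p)
            if ab is not None:
                rows.append((p.input_pg, ab))
        if len(rows) < 3:
            continue
        x = np.array([np.log10(inp) if log_input else inp for inp, _ in rows])
        genera = sorted(set().union(*(ab.keys() for _, ab in rows)))
        stats_rows = []
        for genus in genera:
            y = np.array([ab.get(genus, 0.0) for _, ab in rows])
            if np.ptp(y) == 0:  # constant abundance: no trend by definition
                stats_rows.append((genus, 0.0, 0.0, 1.0))
                continue
            fit = stats.linregress(x, y)
            stats_rows.append((genus, float(fit.slope),
                               float(fit.rvalue ** 2), float(fit.pvalue)))
        pvals = [r[3] for r in stats_rows]
        _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
        for (genus, slope, r2, _), padj in zip(stats_rows, p_adj):
            flag = results.setdefault(genus, EndogenousFlag(genus=genus))
            significant = bool(padj < alpha and r2 > r2_min and slope > 0)
            flag.per_kit[kit] = {
                "slope": slope, "r_squared": r2, "p_adjusted": float(padj),
                "significant": significant,
            }
    for flag in results.values():
        flag.n_kits_significant = sum(
            1 for v in flag.per_kit.values() if v["significant"])
        flag.flagged = flag.n_kits_significant >= min_kits
    return sorted(results.values(), key=lambda f: f.genus)


@dataclass
class ContaminantCatalog:
    """Per-kit core contaminant sets with shared/unique decompositions."""

    core: dict[str, set[str]]
    shared: set[str]
    unique: dict[str, set[str]]


def _prevalent_genera(profiles: Sequence[ReadCountProfile],
                      abundance_min: float,
                      prevalence_min: float) -> set[str]:
    """Genera whose contaminant-normalized abundance exceeds
    ``abundance_min`` in at least ``prevalence_min`` of the libraries."""
    n_libs = len(profiles)
    hits: dict[str, int] = {}
    for p in profiles:
        ab = _contaminant_abundances(p)
        if ab is None:
            continue
        for genus, a in ab.items():
            if a > abundance_min:
                hits[genus] = hits.get(genus, 0) + 1
    return {g for g, n in hits.items() if n / n_libs >= prevalence_min}


def core_contaminants(profiles: Sequence[ReadCountProfile],
                      abundance_min: float = 0.001,
                      prevalence_min: float = 0.5) -> ContaminantCatalog:
    """Per-kit core contaminant catalog.

    A genus is core for a kit when its contaminant-normalized relative
    abundance exceeds ``abundance_min`` (default 0.1%) in at least
    ``prevalence_min`` of that kit's libraries.  ``shared`` is the
    intersection over kits; a kit's ``unique`` set excludes every other
    kit's core genera.
    """
    by_kit: dict[str, list[ReadCountProfile]] = {}
    for p in profiles:
        by_kit.setdefault(p.kit, []).append(p)
    for kit, libs in by_kit.items():
        if len(libs) < 2:
            raise ValueError(f"kit {kit}: need >=2 libraries")
    core = {kit: _prevalent_genera(libs, abundance_min, prevalence_min)
            for kit, libs in sorted(by_kit.items())}
    if all(not s for s in core.values()):
        warnings.warn("no contaminant reads in any library; empty catalog",
                      stacklevel=2)
    kits = list(core)
    shared = set.intersection(*core.values()) if core else set()
    unique = {
        kit: core[kit] - set().union(*(core[k] for k in kits if k != kit))
        if len(kits) > 1 else set(core[kit])
        for kit in kits
    }
    return ContaminantCatalog(core=core, shared=shared, unique=unique)


def dominant_contaminants(profiles: Sequence[ReadCountProfile],
                          abundance_min: float = 0.01,
                          prevalence_min: float = 0.5) -> dict[str, set[str]]:
    """High-abundance contaminants (default >1% in at least half of each
    kit's libraries)."""
    return core_contaminants(profiles, abundance_min=abundance_min,
                             prevalence_min=prevalence_min).core


def remaining_fraction_curve(profile: ReadCountProfile,
                             thresholds: Sequence[float],
                             reference: str = "library",
                             ) -> list[tuple[float, float]]:
    """Fraction of contaminating reads surviving an abundance filter.

    For each threshold ``t``, taxa whose relative abundance (computed over
    the whole library by default, or over contaminating reads only with
    ``reference='contaminant'``) is at least ``t`` are kept; the remaining
    fraction is their share of all contaminating reads.  The curve is
    non-increasing and reaches 0 beyond the most abundant contaminant.
    """
    contam = profile.counts[profile.counts["label"].isin(CONTAMINANT_LABELS)]
    contam_total = contam["reads"].sum()
    if contam_total <= 0:
        raise ValueError(f"{profile.library_id}: no contaminating reads")
    if reference == "library":
        denom = profile.total_depth
    elif reference == "contaminant":
        denom = contam_total
    else:
        raise ValueError(f"unknown reference {reference!r}")
    rel = contam["reads"].to_numpy() / denom
    reads = contam["reads"].to_numpy()
    curve = []
    for t in thresholds:
        remaining = reads[rel >= t].sum() / contam_total
        curve.append((float(t), float(remaining)))
    return curve
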