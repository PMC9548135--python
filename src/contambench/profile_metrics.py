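"""Compositional fidelity, efficiency, and reproducibility metrics.

Abundance profiles are plain ``{taxon: fraction}`` mappings obtained by
total sum scaling of a count table.  The central distance is the
Jensen-Shannon distance (square root of the Jensen-Shannon divergence with
base-2 logarithms), which is bounded on [0, 1] with 0 for identical
compositions; fidelity and reproducibility are ``1 - JSD`` against the
expected composition and between replicates, respectively.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .mock_community import (
    SEQUINS_LABEL,
    CommunityDesign,
    ReadCountProfile,
)

__all__ = [
    "EmptyProfileError",
    "AbundanceProfile",
    "total_sum_scale",
    "normalize",
    "jsd",
    "fidelity",
    "reproducibility",
    "proportion_designated",
    "LibraryQuantification",
    "conversion_rate",
    "duplication_rate",
    "abundance_bias",
    "BiasRegressionResult",
    "length_bias_regression",
    "gc_shift",
    "rarefy",
]

AbundanceProfile = Mapping[str, float]


class EmptyProfileError(ValueError):
    """Normalization was requested on an all-zero selection."""


def total_sum_scale(profile: ReadCountProfile,
                    labels: Sequence[str] | None = None) -> dict[str, float]:
    """Convert counts to relative abundances over the selected labels.

    ``labels=None`` normalizes the whole library; passing e.g.
    ``[SEQUINS_LABEL]`` yields the designated-only composition.
    """
    table = profile.counts
    if labels is not None:
        table = table[table["label"].isin(labels)]
    total = table["reads"].sum()
    if total <= 0:
        raise EmptyProfileError(
            f"{profile.library_id}: no reads in selection {labels}")
    return {t: r / total for t, r in zip(table["taxon"], table["reads"])}


def normalize(abundances: Mapping[str, float]) -> dict[str, float]:
    total = sum(abundances.values())
    if total <= 0:
        raise EmptyProfileError("cannot normalize an all-zero profile")
    return {k: v / total for k, v in abundances.items()}


def jsd(p: AbundanceProfile, q: AbundanceProfile) -> float:
    """Jensen-Shannon distance between two abundance profiles.

    Support is the union of taxa (missing = 0); divergence uses base-2
    logarithms so both divergence and distance lie in [0, 1], with
    ``0 * log 0`` taken as 0.
    """
    support = sorted(set(p) | set(q))
    if not support:
        raise EmptyProfileError("both profiles are empty")
    pa = np.array([p.get(t, 0.0) for t in support], dtype=float)
    qa = np.array([q.get(t, 0.0) for t in support], dtype=float)
    m = 0.5 * (pa + qa)

    def _kl(a: np.ndarray) -> float:
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / m[mask])))

    js = 0.5 * _kl(pa) + 0.5 * _kl(qa)
    return math.sqrt(min(max(js, 0.0), 1.0))


def fidelity(measured: AbundanceProfile, expected: AbundanceProfile) -> float:
    """``1 - JSD`` between a measured and an expected composition."""
    return 1.0 - jsd(measured, expected)


def reproducibility(rep1: AbundanceProfile, rep2: AbundanceProfile) -> float:
    """``1 - JSD`` between the measured profiles of two replicates."""
    return 1.0 - jsd(rep1, rep2)


def proportion_designated(profile: ReadCountProfile) -> float:
    """Fraction of reads originating from the designated (sequins) pool."""
    if profile.total_depth <= 0:
        raise EmptyProfileError(f"{profile.library_id}: zero sequencing depth")
    return profile.sequins_reads / profile.total_depth


@dataclass
class LibraryQuantification:
    """Inputs of the library conversion-rate equation."""

    q_library: float       # measured library quantity, pg
    q_input: float         # input DNA quantity, pg
    n_pcr: int             # PCR cycles
    r_designated: float    # designated-read fraction of all raw reads
    e_primer: float = 2.0  # primer efficiency base (2 = 100%)


def conversion_rate(q: LibraryQuantification) -> float:
    """Fraction of input effectively converted to designated library.

    ``conversion = (Q_library * R_designated) / (Q_input * E_primer ** N_pcr)``
    """
    if q.q_input <= 0:
        raise ValueError("q_input must be positive")
    if q.n_pcr < 0:
        raise ValueError("negative PCR cycle count")
    return (q.q_library * q.r_designated) / (q.q_input * q.e_primer ** q.n_pcr)


def duplication_rate(profile: ReadCountProfile) -> float:
    """Duplicate fraction: ``1 - unique molecules / total reads``."""
    unique = profile.meta.get("n_unique_molecules")
    if unique is None:
        raise ValueError(
            f"{profile.library_id}: no molecule bookkeeping recorded")
    return 1.0 - unique / profile.total_depth


def abundance_bias(measured: AbundanceProfile,
                   reference: AbundanceProfile) -> dict[str, float]:
    """Per-taxon ratio measured/reference abundance (1 = unbiased).

    Taxa with zero reference abundance are skipped with a warning; a ratio
    against nothing is undefined, never infinite.
    """
    ratios: dict[str, float] = {}
    skipped = []
    for taxon, m in measured.items():
        ref = reference.get(taxon, 0.0)
        if ref > 0:
            ratios[taxon] = m / ref
        else:
            skipped.append(taxon)
    if skipped:
        warnings.warn(
            f"abundance_bias: skipped {len(skipped)} taxa with zero "
            f"reference abundance", stacklevel=2)
    return ratios


@dataclass
class BiasRegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def length_bias_regression(bias_ratios: Mapping[str, float],
                           lengths: Mapping[str, float],
                           log_ratio: bool = False) -> BiasRegressionResult:
    """OLS of per-component abundance bias on fragment length.

    Regresses the raw measured/reference ratio (or its natural log with
    ``log_ratio=True``) on length; the p-value is the two-sided slope test.
    """
    taxa = sorted(set(bias_ratios) & set(lengths))
    if len(taxa) < 3:
        raise ValueError("need at least 3 components for the regression")
    x = np.array([lengths[t] for t in taxa], dtype=float)
    y = np.array([bias_ratios[t] for t in taxa], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in lengths")
    if log_ratio:
        if (y <= 0).any():
            raise ValueError("non-positive ratio cannot be log-transformed")
        y = np.log(y)
    fit = stats.linregress(x, y)
    return BiasRegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        p_value=float(fit.pvalue),
    )


def gc_shift(profile: ReadCountProfile, design: CommunityDesign) -> float:
    """Read-weighted mean GC of sequins reads minus the design's
    mass-weighted mean GC; negative values indicate low-GC bias."""
    seq = profile.counts[profile.counts["label"] == SEQUINS_LABEL]
    total = seq["reads"].sum()
    if total <= 0:
        raise EmptyProfileError(f"{profile.library_id}: no sequins reads")
    gc_map = design.gc_by_id
    observed = float(sum(r * gc_map[t]
                         for t, r in zip(seq["taxon"], seq["reads"])) / total)
    return observed - design.mass_weighted_mean_gc()


def rarefy(profile: ReadCountProfile, depth: int,
           seed: int = 0) -> ReadCountProfile:
    """Subsample a profile to ``depth`` reads without replacement.

    Per-taxon counts follow the multivariate hypergeometric distribution, so
    zero taxa stay zero and no count can exceed its original value.
    Molecule bookkeeping does not survive subsampling and is dropped.
    """
    if depth > profile.total_depth:
        raise ValueError(
            f"rarefaction depth {depth} exceeds library depth "
            f"{profile.total_depth}")
    if depth < 0:
        raise ValueError("negative rarefaction depth")
    rng = np.random.default_rng(seed)
    counts = profile.counts["reads"].to_numpy()
    new_counts = rng.multivariate_hypergeometric(counts, depth)
    table = profile.counts.copy()
    table["reads"] = new_counts.astype(int)
    meta = {k: v for k, v in profile.meta.items()
            if k not in ("n_molecules", "n_unique_molecules")}
    out = ReadCountProfile(
        library_id=profile.library_id, kit=profile.kit,
        input_pg=profile.input_pg, replicate=profile.replicate,
        counts=table, total_depth=int(depth), meta=meta)
    out.validate()
    return out
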