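"""In silico decontamination: fold-over-NC filtering and frequency/
prevalence contaminant scoring.

Two families of methods are provided.  The fold-NC rule calls a taxon a true
component when its relative abundance exceeds a fold multiple (5x or 10x) of
its mean abundance across negative controls.  The score-based methods assign
each taxon a frequency score (does its abundance scale inversely with input
DNA, as expected of a fixed-mass reagent contaminant?) and a prevalence
score (is it over-represented in negative controls relative to true
samples?); taxa scoring below a threshold in the chosen mode -- frequency,
prevalence, or either -- are called contaminants.

Score construction: the frequency score compares, on log frequency versus
log input, a contaminant model with slope fixed at -1 (only the intercept is
fitted) against a constant non-contaminant model, and maps the residual
sum-of-squares ratio through the CDF of an F(n-1, n-1) distribution.  The
prevalence score is the one-sided hypergeometric tail probability of seeing
an NC presence count at least as extreme as observed in the 2x2 presence
table.  Small scores are contaminant-like in both cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .mock_community import ReadCountProfile
from .profile_metrics import AbundanceProfile, total_sum_scale

__all__ = [
    "CONTAMINANT",
    "TRUE_COMPONENT",
    "MODES",
    "NCReference",
    "nc_reference",
    "ContaminantCall",
    "fold_nc_classify",
    "frequency_score",
    "prevalence_score",
    "ScorePair",
    "score_table",
    "classify",
]

CONTAMINANT = "contaminant"
TRUE_COMPONENT = "true_component"
MODES = ("frequency", "prevalence", "either")


@dataclass
class NCReference:
    """Mean relative abundance per taxon across negative controls."""

    abundances: dict[str, float]
    n_nc: int


def nc_reference(nc_profiles: Sequence[AbundanceProfile]) -> NCReference:
    """Average the relative abundances of each taxon over the negative
    controls (taxa absent from an NC contribute 0)."""
    if len(nc_profiles) < 2:
        raise ValueError("need at least 2 negative controls")
    support = sorted(set().union(*(p.keys() for p in nc_profiles)))
    n = len(nc_profiles)
    means = {t: sum(p.get(t, 0.0) for p in nc_profiles) / n for t in support}
    return NCReference(abundances=means, n_nc=n)


@dataclass
class ContaminantCall:
    """Per-taxon contaminant/true-component classification."""

    calls: dict[str, str]
    method: str
    params: dict = field(default_factory=dict)

    def contaminants(self) -> set[str]:
        return {t for t, c in self.calls.items() if c == CONTAMINANT}


def fold_nc_classify(profile: AbundanceProfile, ref: NCReference,
                     fold: float = 5.0) -> ContaminantCall:
    """Classify taxa by fold change over the NC reference.

    A taxon is a true component iff its abundance is *strictly* greater
    than ``fold`` times its NC reference abundance; everything else
    (including exact ties and zero-abundance taxa) is a contaminant.  Taxa
    absent from all NCs are vacuously above any fold of zero whenever
    present.
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    calls = {}
    for taxon, abundance in profile.items():
        threshold = fold * ref.abundances.get(taxon, 0.0)
        is_true = abundance > threshold and abundance > 0
        calls[taxon] = TRUE_COMPONENT if is_true else CONTAMINANT
    return ContaminantCall(calls=calls, method=f"fold{fold:g}-NC",
                           params={"fold": fold, "n_nc": ref.n_nc})


def frequency_score(frequencies: Sequence[float],
                    input_masses: Sequence[float]) -> float | None:
    """Score how contaminant-like a taxon's frequency/input relationship is.

    Only samples where the taxon is present (frequency > 0) enter the fit;
    fewer than 3 such samples leaves the score undefined (None).  On
    ``x = ln input``, ``y = ln frequency``, the contaminant model is
    ``y = -x + b`` (b by least squares) and the null model is ``y = const``;
    the score is ``F_{n-1,n-1}.cdf(SSR_contaminant / SSR_null)``, so scores
    near 0 indicate the inverse-input (contaminant) pattern.
    """
    f = np.asarray(frequencies, dtype=float)
    x_all = np.asarray(input_masses, dtype=float)
    if f.shape != x_all.shape:
        raise ValueError("frequencies and input masses differ in length")
    mask = f > 0
    n = int(mask.sum())
    if n < 3:
        return None
    x = np.log(x_all[mask])
    y = np.log(f[mask])
    b = np.mean(y + x)
    ssr_contam = float(np.sum((y + x - b) ** 2))
    ssr_null = float(np.sum((y - np.mean(y)) ** 2))
    if ssr_contam == 0.0:
        return 0.0
    if ssr_null == 0.0:
        return 1.0
    return float(stats.f.cdf(ssr_contam / ssr_null, n - 1, n - 1))


def prevalence_score(present_pos: int, n_pos: int,
                     present_nc: int, n_nc: int) -> float:
    """One-sided hypergeometric tail for NC over-representation.

    Under the null that presences are exchangeable across the
    ``n_pos + n_nc`` samples, returns ``P(X >= present_nc)`` where X is the
    NC presence count given ``present_pos + present_nc`` presences in total.
    Small values mean the taxon is concentrated in negative controls.
    """
    if n_pos < 1 or n_nc < 1:
        raise ValueError("need at least one positive sample and one NC")
    if not (0 <= present_pos <= n_pos and 0 <= present_nc <= n_nc):
        raise ValueError("presence counts exceed sample counts")
    total_present = present_pos + present_nc
    return float(stats.hypergeom.sf(present_nc - 1, n_pos + n_nc,
                                    total_present, n_nc))


@dataclass
class ScorePair:
    """Frequency and prevalence scores for one taxon (None = undefined)."""

    taxon: str
    score_freq: float | None
    score_prev: float | None
    present_in_positives: bool = True


def score_table(positive_profiles: Sequence[ReadCountProfile],
                nc_profiles: Sequence[ReadCountProfile],
                presence_floor: float = 0.0) -> list[ScorePair]:
    """Score every taxon observed across a kit's libraries.

    Frequencies are whole-library relative abundances in the positive
    samples (negative controls are excluded from the frequency fit);
    presence means relative abundance strictly above ``presence_floor``
    (0 by default, i.e. any read).
    """
    if not positive_profiles or not nc_profiles:
        raise ValueError("need positive samples and negative controls")
    pos_ab = [total_sum_scale(p) for p in positive_profiles]
    nc_ab = [total_sum_scale(p) for p in nc_profiles]
    inputs = np.array([p.input_pg for p in positive_profiles], dtype=float)
    taxa = sorted(set().union(*(a.keys() for a in pos_ab + nc_ab)))
    n_pos, n_nc = len(pos_ab), len(nc_ab)
    pairs = []
    for taxon in taxa:
        freqs = np.array([a.get(taxon, 0.0) for a in pos_ab])
        present_pos = int(np.sum(freqs > presence_floor))
        present_nc = sum(a.get(taxon, 0.0) > presence_floor for a in nc_ab)
        pairs.append(ScorePair(
            taxon=taxon,
            score_freq=frequency_score(freqs, inputs),
            score_prev=prevalence_score(present_pos, n_pos,
                                        int(present_nc), n_nc),
            present_in_positives=present_pos > 0,
        ))
    return pairs


def classify(pairs: Sequence[ScorePair], mode: str,
             t_freq: float = 0.5, t_prev: float = 0.5) -> ContaminantCall:
    """Threshold the scores into contaminant calls.

    Contaminant iff ``score < threshold`` (strict) for the mode's score, or
    for either score in ``either`` mode.  Undefined scores never trigger a
    contaminant call; taxa never seen in any positive sample are called
    contaminants by convention (they carry no signal reads).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    calls = {}
    for pair in pairs:
        if not pair.present_in_positives:
            calls[pair.taxon] = CONTAMINANT
            continue
        by_freq = pair.score_freq is not None and pair.score_freq < t_freq
        by_prev = pair.score_prev is not None and pair.score_prev < t_prev
        if mode == "frequency":
            is_contam = by_freq
        elif mode == "prevalence":
            is_contam = by_prev
        else:
            is_contam = by_freq or by_prev
        calls[pair.taxon] = CONTAMINANT if is_contam else TRUE_COMPONENT
    return ContaminantCall(calls=calls, method=f"decontam-{mode}",
                           params={"t_freq": t_freq, "t_prev": t_prev,
                                   "mode": mode})
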