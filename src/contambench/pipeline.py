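"""End-to-end benchmark: simulate -> metrics -> contaminant
characterization -> decontamination -> read-weighted evaluation.

Mirrors the evaluation flow of a mock-community dilution-series study:
libraries are simulated for every (kit, input, replicate) plus negative
controls; fidelity/efficiency/reproducibility metrics are computed per
library; endogenous contaminants are screened and filtered; contaminants
are quantified absolutely via the spike-in ratio and cataloged; and each
decontamination method is scored per read against the simulation truth.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .config import RunConfig, config_hash
from .contaminant_quant import (
    NotQuantifiableError,
    core_contaminants,
    detect_endogenous,
    dominant_contaminants,
    quantify_contaminant_mass,
    remaining_fraction_curve,
)
from .decontam_methods import (
    classify,
    fold_nc_classify,
    nc_reference,
    score_table,
)
from .evaluation import (
    confusion,
    decontaminated_jsd,
    optimize_threshold,
    permanova,
    precision_recall,
    threshold_grid,
)
from .io import (
    write_config,
    write_design,
    write_json,
    write_pools,
    write_profiles,
)
from .mock_community import (
    CONTAMINANT_LABELS,
    SEQUINS_LABEL,
    BiasModel,
    EndogenousModel,
    ReadCountProfile,
    build_design,
    default_pools,
    derive_seed,
    simulate_experiment,
)
from .profile_metrics import (
    EmptyProfileError,
    LibraryQuantification,
    conversion_rate,
    duplication_rate,
    fidelity,
    jsd,
    proportion_designated,
    reproducibility,
    total_sum_scale,
)

__all__ = ["run_pipeline"]

logger = logging.getLogger("contambench")

#: Abundance thresholds for the remaining-contaminant curves.
REMAINING_THRESHOLDS = (0.0, 1e-5, 5e-5, 1e-4, 5e-4, 1e-3, 5e-3,
                        1e-2, 5e-2, 1e-1)


def _library_metrics(profile: ReadCountProfile, design) -> dict:
    row = {
        "library_id": profile.library_id,
        "kit": profile.kit,
        "input_pg": profile.input_pg,
        "replicate": profile.replicate,
        "total_depth": profile.total_depth,
        "proportion_designated": proportion_designated(profile),
        "duplication_rate": duplication_rate(profile),
        "planted_kit_contaminant_pg": profile.meta.get(
            "kit_contaminant_mass_pg"),
        "planted_endogenous_pg": profile.meta.get("endogenous_mass_pg"),
    }
    expected = design.mass_fractions
    if profile.input_pg > 0:
        try:
            row["fidelity_full"] = fidelity(total_sum_scale(profile), expected)
            row["fidelity_sequins"] = fidelity(
                total_sum_scale(profile, labels=[SEQUINS_LABEL]), expected)
        except EmptyProfileError:
            row["fidelity_full"] = row["fidelity_sequins"] = None
        q = LibraryQuantification(
            q_library=profile.meta["library_yield_pg"],
            q_input=profile.input_pg,
            n_pcr=profile.meta["n_pcr_cycles"],
            r_designated=row["proportion_designated"])
        row["conversion_rate"] = conversion_rate(q)
        try:
            row["contaminant_mass_pg"] = quantify_contaminant_mass(
                profile).mass_pg
        except NotQuantifiableError:
            row["contaminant_mass_pg"] = None
    else:
        row["fidelity_full"] = row["fidelity_sequins"] = None
        row["conversion_rate"] = None
        row["contaminant_mass_pg"] = None
    return row


def _replicate_rows(profiles: Sequence[ReadCountProfile]) -> list[dict]:
    groups: dict[tuple, list[ReadCountProfile]] = {}
    for p in profiles:
        if p.input_pg > 0:
            groups.setdefault((p.kit, p.input_pg), []).append(p)
    rows = []
    for (kit, input_pg), libs in sorted(groups.items()):
        if len(libs) < 2:
            continue
        a, b = sorted(libs, key=lambda p: p.replicate)[:2]
        row = {"kit": kit, "input_pg": input_pg}
        try:
            row["reproducibility_sequins"] = reproducibility(
                total_sum_scale(a, labels=[SEQUINS_LABEL]),
                total_sum_scale(b, labels=[SEQUINS_LABEL]))
        except EmptyProfileError:
            row["reproducibility_sequins"] = None
        try:
            row["contaminant_replicate_jsd"] = jsd(
                total_sum_scale(a, labels=list(CONTAMINANT_LABELS)),
                total_sum_scale(b, labels=list(CONTAMINANT_LABELS)))
        except EmptyProfileError:
            row["contaminant_replicate_jsd"] = None
        rows.append(row)
    return rows


def _contaminant_distance_matrix(profiles: Sequence[ReadCountProfile]):
    """JSD matrix over contaminant-normalized compositions of the positive
    libraries that contain contaminating reads."""
    kept = []
    comps = []
    for p in profiles:
        if p.input_pg <= 0:
            continue
        try:
            comps.append(total_sum_scale(p, labels=list(CONTAMINANT_LABELS)))
            kept.append(p)
        except EmptyProfileError:
            continue
    n = len(kept)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = jsd(comps[i], comps[j])
    return dist, kept


def _permanova_block(profiles, factor: str, n_permutations: int,
                     seed: int) -> dict | None:
    dist, kept = _contaminant_distance_matrix(profiles)
    if len(kept) < 3:
        return None
    labels = [getattr(p, "kit" if factor == "kit" else "input_pg")
              for p in kept]
    if len(set(labels)) < 2:
        return None
    res = permanova(dist, labels, n_permutations=n_permutations, seed=seed)
    return {"r_squared": res.r_squared, "pseudo_f": res.pseudo_f,
            "p_value": res.p_value, "n": len(kept)}


def _evaluate_kit(kit: str, profiles: Sequence[ReadCountProfile],
                  methods: Sequence[str], grid) -> dict | None:
    positives = [p for p in profiles if p.input_pg > 0]
    ncs = [p for p in profiles if p.input_pg == 0]
    if not positives or len(ncs) < 2:
        return None
    pairs = score_table(positives, ncs)
    truth: dict[str, bool] = {}
    reads: dict[str, int] = {}
    for p in positives:
        for taxon, label, r in zip(p.counts["taxon"], p.counts["label"],
                                   p.counts["reads"]):
            truth[taxon] = label != SEQUINS_LABEL
            reads[taxon] = reads.get(taxon, 0) + int(r)
    for pair in pairs:  # NC-only taxa carry no positive reads
        truth.setdefault(pair.taxon, True)
        reads.setdefault(pair.taxon, 0)

    sweep_freq = optimize_threshold(pairs, reads, truth, "frequency", grid)
    sweep_prev = optimize_threshold(pairs, reads, truth, "prevalence", grid)
    nc_ref = nc_reference([total_sum_scale(p) for p in ncs])

    kit_calls = {
        "frequency": classify(pairs, "frequency", t_freq=sweep_freq.chosen),
        "prevalence": classify(pairs, "prevalence", t_prev=sweep_prev.chosen),
        "either": classify(pairs, "either", t_freq=sweep_freq.chosen,
                           t_prev=sweep_prev.chosen),
    }

    per_method: dict[str, list[dict]] = {}
    for method in methods:
        rows = []
        for p in positives:
            if method in ("fold5", "fold10"):
                fold = 5.0 if method == "fold5" else 10.0
                call = fold_nc_classify(total_sum_scale(p), nc_ref, fold=fold)
            else:
                call = kit_calls[method]
            c = confusion(call, p)
            prec, rec = precision_recall(c)
            try:
                jsd_before = jsd(total_sum_scale(p),
                                 total_sum_scale(p, labels=[SEQUINS_LABEL]))
                jsd_after = decontaminated_jsd(p, call)
            except EmptyProfileError:
                jsd_before = jsd_after = None
            rows.append({
                "library_id": p.library_id,
                "input_pg": p.input_pg,
                "tp": c.tp, "fn": c.fn, "tn": c.tn, "fp": c.fp,
                "precision": prec, "recall": rec,
                "jsd_before": jsd_before, "jsd_after": jsd_after,
            })
        per_method[method] = rows

    return {
        "thresholds": {
            "frequency": sweep_freq.chosen,
            "prevalence": sweep_prev.chosen,
            "frequency_full_precision": sweep_freq.full_precision_attained,
            "prevalence_full_precision": sweep_prev.full_precision_attained,
        },
        "methods": per_method,
    }


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute all stages and return the run report as a plain dict.

    Deterministic given ``config.seed``; when ``out_dir`` is given, the
    design, pools, profiles, config, and report are written there.
    """
    config.validate()
    chash = config_hash(config)
    logger.info("run start: seed=%s config=%s", config.seed, chash)

    design = build_design(config.n_components, config.n_tiers,
                          seed=derive_seed(config.seed, "design"))
    pools = default_pools(seed=config.seed,
                          load_medians=config.load_medians_pg,
                          load_dispersion=config.load_dispersion,
                          genus_sigma=config.genus_sigma,
                          profile_sigma=config.profile_sigma,
                          kits=config.kits)
    bias = BiasModel(**config.bias)
    endo = EndogenousModel(mass_fraction_of_input=config.endo_mass_fraction)
    profiles = simulate_experiment(
        design, kits=config.kits, dilution_series=config.dilution_series_pg,
        replicates=config.replicates, pools=pools, bias=bias,
        seed=config.seed, depth=config.depth, n_nc=config.n_nc, endo=endo,
        wga=config.wga)
    logger.info("simulated %d libraries", len(profiles))

    library_rows = [_library_metrics(p, design) for p in profiles]
    replicate_rows = _replicate_rows(profiles)

    # Endogenous screen, then filter flagged genera from everything
    # downstream (contamination analyses and decontamination evaluation).
    endo_report: dict = {"skipped": False, "flagged": [], "flags": []}
    try:
        flags = detect_endogenous(profiles)
        flagged = {f.genus for f in flags if f.flagged}
        endo_report["flagged"] = sorted(flagged)
        endo_report["flags"] = [
            {"genus": f.genus, "n_kits_significant": f.n_kits_significant,
             "flagged": f.flagged}
            for f in flags]
    except ValueError as exc:
        endo_report = {"skipped": True, "reason": str(exc),
                       "flagged": [], "flags": []}
        flagged = set()
    filtered = ([p.drop_taxa(flagged) for p in profiles]
                if flagged else list(profiles))
    logger.info("endogenous screen: %d genera flagged", len(flagged))

    permanova_report = {
        "kit": _permanova_block(profiles, "kit",
                                config.permanova_permutations,
                                derive_seed(config.seed, "permanova:kit")),
        "input_before_filter": _permanova_block(
            profiles, "input", config.permanova_permutations,
            derive_seed(config.seed, "permanova:input")),
        "input_after_filter": _permanova_block(
            filtered, "input", config.permanova_permutations,
            derive_seed(config.seed, "permanova:input:filtered")),
    }

    estimates: dict[str, list[float]] = {}
    for p in filtered:
        if p.input_pg > 0:
            try:
                est = quantify_contaminant_mass(p)
            except NotQuantifiableError:
                continue
            estimates.setdefault(p.kit, []).append(est.mass_pg)
    quant_report = {
        "per_kit_median_pg": {k: float(np.median(v))
                              for k, v in sorted(estimates.items())},
    }

    try:
        catalog = core_contaminants(filtered)
        dominant = dominant_contaminants(filtered)
        catalog_report = {
            "core": {k: sorted(v) for k, v in catalog.core.items()},
            "shared": sorted(catalog.shared),
            "unique": {k: sorted(v) for k, v in catalog.unique.items()},
            "dominant": {k: sorted(v) for k, v in dominant.items()},
        }
    except ValueError as exc:
        catalog_report = {"skipped": True, "reason": str(exc)}

    curves = {}
    for kit in config.kits:
        kit_pos = [p for p in filtered
                   if p.kit == kit and p.input_pg > 0]
        if not kit_pos:
            continue
        lowest = min(kit_pos, key=lambda p: (p.input_pg, p.replicate))
        try:
            curves[kit] = remaining_fraction_curve(
                lowest, REMAINING_THRESHOLDS)
        except ValueError:
            continue

    grid = threshold_grid(config.grid_n, config.grid_lo, config.grid_hi)
    decontam_report = {}
    for kit in config.kits:
        kit_profiles = [p for p in filtered if p.kit == kit]
        block = _evaluate_kit(kit, kit_profiles, config.methods, grid)
        if block is not None:
            decontam_report[kit] = block
    logger.info("evaluated decontamination on %d kits", len(decontam_report))

    report = {
        "provenance": {
            "package": "contambench",
            "version": __version__,
            "seed": config.seed,
            "config_hash": chash,
        },
        "design": {"n_components": len(design.components),
                   "n_tiers": design.n_tiers},
        "libraries": library_rows,
        "reproducibility": replicate_rows,
        "endogenous": endo_report,
        "permanova": permanova_report,
        "quantification": quant_report,
        "catalog": catalog_report,
        "remaining_curves": curves,
        "decontamination": decontam_report,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_config(config, out / "config.json")
        write_design(design, out / "design.json")
        write_pools(pools, out / "pools.json")
        write_profiles(profiles, out / "profiles.tsv")
        write_json(report, out / "report.json")
        logger.info("artifacts written to %s", out)
    return report
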