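"""TSV/JSON/YAML serialization of designs, pools, profiles, and reports.

Profiles travel as a flat TSV (one row per library x taxon with provenance
label) plus a JSON sidecar carrying per-library simulator bookkeeping, so
the pair round-trips losslessly while the TSV alone stays diff-able and
language-neutral.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .config import RunConfig
from .mock_community import (
    CommunityDesign,
    ContaminantPool,
    ReadCountProfile,
)

__all__ = [
    "ProfileParseError",
    "PROFILE_COLUMNS",
    "write_design", "read_design",
    "write_pools", "read_pools",
    "write_profiles", "read_profiles",
    "write_config", "read_config",
    "write_json", "read_json",
]

PROFILE_COLUMNS = ("library_id", "kit", "input_pg", "replicate",
                   "taxon", "label", "reads")


class ProfileParseError(ValueError):
    """A profile TSV row failed validation (message carries the line)."""


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def write_design(design: CommunityDesign, path: str | Path) -> None:
    write_json(design.to_dict(), path)


def read_design(path: str | Path) -> CommunityDesign:
    return CommunityDesign.from_dict(read_json(path))


def write_pools(pools: dict[str, ContaminantPool], path: str | Path) -> None:
    write_json({kit: pool.to_dict() for kit, pool in pools.items()}, path)


def read_pools(path: str | Path) -> dict[str, ContaminantPool]:
    raw = read_json(path)
    return {kit: ContaminantPool.from_dict(d) for kit, d in raw.items()}


def _meta_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_name(p.name + ".meta.json")


def write_profiles(profiles: Sequence[ReadCountProfile],
                   path: str | Path) -> None:
    """Write profiles as TSV plus a ``<path>.meta.json`` bookkeeping sidecar."""
    rows = []
    meta = {}
    for p in profiles:
        for taxon, label, reads in zip(p.counts["taxon"], p.counts["label"],
                                       p.counts["reads"]):
            rows.append((p.library_id, p.kit, p.input_pg, p.replicate,
                         taxon, label, int(reads)))
        meta[p.library_id] = {"total_depth": p.total_depth, "meta": p.meta}
    frame = pd.DataFrame(rows, columns=list(PROFILE_COLUMNS))
    frame.to_csv(path, sep="\t", index=False)
    write_json(meta, _meta_path(path))


def read_profiles(path: str | Path) -> list[ReadCountProfile]:
    """Read a profile TSV (and its meta sidecar when present)."""
    try:
        frame = pd.read_csv(path, sep="\t", dtype={
            "library_id": str, "kit": str, "taxon": str, "label": str})
    except (pd.errors.ParserError, ValueError) as exc:
        raise ProfileParseError(f"{path}: {exc}") from exc
    missing = set(PROFILE_COLUMNS) - set(frame.columns)
    if missing:
        raise ProfileParseError(f"{path}: missing columns {sorted(missing)}")
    for col, caster in (("input_pg", float), ("replicate", int),
                        ("reads", int)):
        for idx, value in frame[col].items():
            try:
                caster(value)
            except (TypeError, ValueError):
                # +2: one for the header, one for 1-based numbering
                raise ProfileParseError(
                    f"{path}: line {idx + 2}: bad {col} value {value!r}"
                ) from None
    if (frame["reads"].astype(int) < 0).any():
        bad = frame.index[frame["reads"].astype(int) < 0][0]
        raise ProfileParseError(f"{path}: line {bad + 2}: negative reads")

    meta_file = _meta_path(path)
    meta = read_json(meta_file) if meta_file.exists() else {}
    profiles = []
    for lib_id, group in frame.groupby("library_id", sort=False):
        counts = group[["taxon", "label", "reads"]].reset_index(drop=True)
        counts["reads"] = counts["reads"].astype(int)
        lib_meta = meta.get(lib_id, {})
        profile = ReadCountProfile(
            library_id=str(lib_id),
            kit=str(group["kit"].iloc[0]),
            input_pg=float(group["input_pg"].iloc[0]),
            replicate=int(group["replicate"].iloc[0]),
            counts=counts,
            total_depth=int(lib_meta.get("total_depth",
                                         counts["reads"].sum())),
            meta=dict(lib_meta.get("meta", {})),
        )
        profile.validate()
        profiles.append(profile)
    return profiles


def write_config(config: RunConfig, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    else:
        write_json(config.to_dict(), path)


def read_config(path: str | Path) -> RunConfig:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        raw = yaml.safe_load(path.read_text())
    else:
        raw = read_json(path)
    return RunConfig.from_dict(raw)
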