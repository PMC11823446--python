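"""On-disk formats: counts/metadata TSV, GMT gene sets, tile CSV, anchors,
and provenance headers tying every artifact to its inputs and seed."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .ivive import InVivoAnchor
from .synth import CountMatrix


def write_counts(cm: CountMatrix, counts_path: str | Path, meta_path: str | Path) -> None:
    """Counts TSV (probes x samples, attenuation_factor column first) plus a
    sample-metadata TSV."""
    out = cm.counts.copy()
    out.insert(0, "attenuation_factor", cm.attenuation)
    out.to_csv(counts_path, sep="\t")
    cm.sample_meta.to_csv(meta_path, sep="\t")


def read_counts(counts_path: str | Path, meta_path: str | Path) -> CountMatrix:
    tbl = pd.read_csv(counts_path, sep="\t", index_col=0)
    if "attenuation_factor" in tbl.columns:
        att = tbl.pop("attenuation_factor")
    else:
        att = pd.Series(1.0, index=tbl.index, name="attenuation_factor")
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return CountMatrix(counts=tbl.astype(int), attenuation=att.astype(float),
                       sample_meta=meta)


def write_gmt(genesets: dict[str, list[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    """Standard GMT: one set per line — name, description, tab-joined members."""
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in genesets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[fields[0]] = fields[2:]
    return sets


def write_tiles(tiles: pd.DataFrame, path: str | Path) -> None:
    tiles.to_csv(path, index=False)


def read_tiles(path: str | Path) -> pd.DataFrame:
    tiles = pd.read_csv(path)
    required = {"well_id", "substance", "concentration", "tile_index", "score"}
    missing = required - set(tiles.columns)
    if missing:
        raise ValueError(f"tile CSV missing columns: {sorted(missing)}")
    return tiles


def read_anchors(path: str | Path) -> list[InVivoAnchor]:
    """Anchor CSV: substance, loel_plasma, loel_dose, ref_dose,
    plasma_at_ref_dose, clearance_fraction, mw (blank fields optional)."""
    tbl = pd.read_csv(path)
    anchors = []
    for _, row in tbl.iterrows():
        def opt(col):
            v = row.get(col)
            return None if pd.isna(v) else float(v)

        anchors.append(
            InVivoAnchor(
                substance=str(row["substance"]),
                loel_plasma=opt("loel_plasma"),
                loel_dose=opt("loel_dose"),
                ref_dose=opt("ref_dose"),
                plasma_at_ref_dose=opt("plasma_at_ref_dose"),
                clearance_fraction_24h=opt("clearance_fraction") or 0.0,
                mw=opt("mw"),
                source=str(row.get("source", "")),
            )
        )
    return anchors


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(
    path: str | Path,
    stage: str,
    inputs: list[str | Path],
    params: dict,
    seed: int | None,
) -> None:
    """Provenance JSON: hashed inputs, parameters, seed and versions."""
    import hepapod

    record = {
        "stage": stage,
        "inputs": {str(p): file_sha256(p) for p in inputs if Path(p).exists()},
        "params": params,
        "seed": seed,
        "versions": {"hepapod": hepapod.__version__},
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
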