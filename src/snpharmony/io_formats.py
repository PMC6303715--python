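"""Reading and writing genotype panels and sidecar tables.

Supported formats:

* **Genepop** — population-blocked, 4-digit diploid codes, alleles coded
  ``01..04 = A,C,G,T`` and ``00`` missing.  The title line documents the code
  mapping and carries a machine-readable ``alleles=`` annotation so that
  nucleotide identity (needed for ambiguity classification) survives a
  round-trip even for loci monomorphic in the file.  On load the designated
  allele is the lower allele code.
* **VCF** — only CHROM/POS/ID/REF/ALT/GT are consumed; everything else is
  ignored on read and minimally emitted on write (via pysam).  REF is the
  designated allele.

Sample metadata travels in a sidecar CSV (columns ``individual_id,
location_code, dataset, lat, lon``); coordinates are decimal degrees WGS84
and are never used for distance computation — distances are supplied as a
square CSV keyed by location code.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .panel import (
    BASES,
    MISSING,
    DistanceMatrix,
    GenotypePanel,
    LocusDef,
    PanelError,
    SampleUnit,
)

__all__ = [
    "load_panel",
    "write_panel",
    "load_metadata",
    "write_metadata",
    "load_distance_matrix",
    "write_distance_matrix",
    "PanelFormatError",
]

_ALLELE_CODE = {b: f"{i + 1:02d}" for i, b in enumerate(BASES)}
_CODE_ALLELE = {v: k for k, v in _ALLELE_CODE.items()}
_CODE_ORDER = {b: i for i, b in enumerate(BASES)}


class PanelFormatError(PanelError):
    """File does not parse under the named standard."""


# --------------------------------------------------------------------- metadata
def load_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"individual_id": str, "location_code": str, "dataset": str})
    required = {"individual_id", "location_code", "dataset"}
    missing = required - set(df.columns)
    if missing:
        raise PanelFormatError(f"metadata {path}: missing columns {sorted(missing)}")
    if df["individual_id"].duplicated().any():
        dup = df.loc[df["individual_id"].duplicated(), "individual_id"].iloc[0]
        raise PanelFormatError(f"metadata {path}: duplicate individual_id {dup!r}")
    return df


def write_metadata(panel: GenotypePanel, path: str | Path) -> None:
    loc_meta = {s.location_code: s for s in panel.samples}
    rows = []
    for ind_id, loc in panel.individuals:
        s = loc_meta[loc]
        rows.append(
            {
                "individual_id": ind_id,
                "location_code": loc,
                "dataset": s.dataset,
                "lat": s.latitude,
                "lon": s.longitude,
            }
        )
    pd.DataFrame(rows, columns=["individual_id", "location_code", "dataset", "lat", "lon"]).to_csv(
        path, index=False
    )


def _samples_from_metadata(
    meta: pd.DataFrame, individuals: Sequence[tuple[str, str]]
) -> list[SampleUnit]:
    meta = meta.set_index("individual_id")
    used_locs: dict[tuple[str, str], int] = {}
    coords: dict[tuple[str, str], tuple[float | None, float | None]] = {}
    for ind_id, loc in individuals:
        row = meta.loc[ind_id]
        key = (loc, str(row["dataset"]))
        used_locs[key] = used_locs.get(key, 0) + 1
        lat = row.get("lat")
        lon = row.get("lon")
        coords[key] = (
            None if pd.isna(lat) else float(lat),
            None if pd.isna(lon) else float(lon),
        )
    return [
        SampleUnit(loc, ds, n, coords[(loc, ds)][0], coords[(loc, ds)][1])
        for (loc, ds), n in used_locs.items()
    ]


def _location_of(meta: pd.DataFrame, path: str | Path) -> Mapping[str, str]:
    table = meta.set_index("individual_id")["location_code"]

    def lookup(ind_id: str) -> str:
        if ind_id not in table.index:
            raise PanelError(
                f"{path}: individual {ind_id!r} absent from metadata"
            )
        return str(table.loc[ind_id])

    return lookup  # type: ignore[return-value]


# ---------------------------------------------------------------------- genepop
def _genepop_title(panel: GenotypePanel) -> str:
    ann = ",".join(f"{l.locus_id}:{l.allele_pair[0]}{l.allele_pair[1]}" for l in panel.loci)
    return (
        "snpharmony genepop export; allele codes 01=A 02=C 03=G 04=T; "
        f"alleles={ann}"
    )


def _write_genepop(panel: GenotypePanel, path: Path) -> None:
    # Genepop convention: designated allele = lower allele code, so emit the
    # canonical designation and keep the true pair in the title annotation.
    canon = panel.canonicalized()
    lines = [_genepop_title(panel)]
    lines.extend(l.locus_id for l in canon.loci)
    by_block: dict[tuple[str, str], list[int]] = {}
    loc_ds = {s.location_code: s.dataset for s in canon.samples}
    for i, (_, loc) in enumerate(canon.individuals):
        by_block.setdefault((loc_ds[loc], loc), []).append(i)
    for (_, loc), rows in by_block.items():
        lines.append("Pop")
        for i in rows:
            codes = []
            for j, locus in enumerate(canon.loci):
                g = canon.dosages[i, j]
                c1 = _ALLELE_CODE[locus.allele_pair[0]]
                c2 = _ALLELE_CODE[locus.allele_pair[1]]
                if g == MISSING:
                    codes.append("0000")
                elif g == 2:
                    codes.append(c1 + c1)
                elif g == 1:
                    codes.append(c1 + c2)
                else:
                    codes.append(c2 + c2)
            lines.append(f"{canon.individuals[i][0]} ,  " + " ".join(codes))
    path.write_text("\n".join(lines) + "\n")


def _parse_genepop(path: Path, meta: pd.DataFrame) -> GenotypePanel:
    text = path.read_text().splitlines()
    if not text:
        raise PanelFormatError(f"{path}: empty file (line 1)")
    title = text[0]
    annotated: dict[str, tuple[str, str]] = {}
    m = re.search(r"alleles=([A-Za-z0-9_.:,-]+)", title)
    if m:
        for item in m.group(1).split(","):
            lid, _, pair = item.rpartition(":")
            if lid and len(pair) == 2:
                annotated[lid] = (pair[0].upper(), pair[1].upper())

    locus_names: list[str] = []
    i = 1
    while i < len(text) and text[i].strip().lower() != "pop":
        line = text[i].strip()
        if line:
            locus_names.extend(n.strip() for n in line.split(",") if n.strip())
        i += 1
    if i == len(text):
        if locus_names or len(text) == 1:
            # Header-only file: a valid degenerate panel with no individuals.
            loci = [
                LocusDef(n, annotated.get(n, ("A", "C"))) for n in locus_names
            ]
            return GenotypePanel(loci, [], [], np.zeros((0, len(loci)), dtype=np.int8))
        raise PanelFormatError(f"{path}: no 'Pop' line found (line {len(text)})")

    individuals: list[str] = []
    genotype_rows: list[list[str]] = []
    for lineno in range(i, len(text)):
        line = text[lineno].strip()
        if not line:
            continue
        if line.lower() == "pop":
            continue
        if "," not in line:
            raise PanelFormatError(
                f"{path}: line {lineno + 1}: expected 'id , genotypes'"
            )
        ind_id, _, rest = line.partition(",")
        codes = rest.split()
        if len(codes) != len(locus_names):
            raise PanelFormatError(
                f"{path}: line {lineno + 1}: {len(codes)} genotypes for "
                f"{len(locus_names)} loci"
            )
        for c in codes:
            if not re.fullmatch(r"\d{4}", c):
                raise PanelFormatError(
                    f"{path}: line {lineno + 1}: bad 4-digit code {c!r}"
                )
        individuals.append(ind_id.strip())
        genotype_rows.append(codes)

    # Recover allele pairs: annotation wins; otherwise infer from the codes.
    observed: list[set[str]] = [set() for _ in locus_names]
    for codes in genotype_rows:
        for j, c in enumerate(codes):
            for half in (c[:2], c[2:]):
                if half != "00":
                    if half not in _CODE_ALLELE:
                        raise PanelFormatError(
                            f"{path}: allele code {half!r} outside 01-04 at locus "
                            f"{locus_names[j]!r}"
                        )
                    observed[j].add(_CODE_ALLELE[half])

    loci: list[LocusDef] = []
    for j, name in enumerate(locus_names):
        if name in annotated:
            pair = annotated[name]
        else:
            obs = sorted(observed[j], key=_CODE_ORDER.get)
            if len(obs) == 2:
                pair = (obs[0], obs[1])
            else:
                raise PanelFormatError(
                    f"{path}: locus {name!r} is not biallelic in the file and no "
                    "alleles= annotation is present"
                )
        # Designated allele = lower allele code.
        a, b = sorted(pair, key=_CODE_ORDER.get)
        loci.append(LocusDef(name, (a, b)))
        if not observed[j] <= set(pair):
            raise PanelFormatError(
                f"{path}: locus {name!r}: observed alleles {sorted(observed[j])} "
                f"outside annotated pair {pair}"
            )

    dosages = np.full((len(individuals), len(locus_names)), MISSING, dtype=np.int8)
    for r, codes in enumerate(genotype_rows):
        for j, c in enumerate(codes):
            if c == "0000":
                continue
            a1, a2 = _CODE_ALLELE[c[:2]], _CODE_ALLELE[c[2:]]
            designated = loci[j].allele_pair[0]
            dosages[r, j] = (a1 == designated) + (a2 == designated)

    locate = _location_of(meta, path)
    inds = [(ind, locate(ind)) for ind in individuals]
    return GenotypePanel(loci, _samples_from_metadata(meta, inds), inds, dosages)


# -------------------------------------------------------------------------- vcf
def _write_vcf(panel: GenotypePanel, path: Path) -> None:
    header = pysam.VariantHeader()
    contigs = []
    for locus in panel.loci:
        c = locus.linkage_group or "UN"
        if c not in contigs:
            contigs.append(c)
    if not contigs:
        contigs = ["UN"]
    for c in contigs:
        header.add_line(f"##contig=<ID={c}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for ind_id, _ in panel.individuals:
        header.add_sample(ind_id)
    pos_counter = {c: 0 for c in contigs}
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for j, locus in enumerate(panel.loci):
            contig = locus.linkage_group or "UN"
            pos_counter[contig] += 1
            rec = vf.new_record(
                contig=contig,
                start=pos_counter[contig] - 1,
                alleles=(locus.allele_pair[0], locus.allele_pair[1]),
                id=locus.locus_id,
            )
            for i, (ind_id, _) in enumerate(panel.individuals):
                g = panel.dosages[i, j]
                if g == MISSING:
                    rec.samples[ind_id]["GT"] = (None, None)
                else:
                    rec.samples[ind_id]["GT"] = (
                        (0, 0) if g == 2 else (0, 1) if g == 1 else (1, 1)
                    )
            vf.write(rec)


def _parse_vcf(path: Path, meta: pd.DataFrame) -> GenotypePanel:
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise PanelFormatError(f"{path}: not a parseable VCF: {exc}") from exc
    with vf:
        sample_names = list(vf.header.samples)
        loci: list[LocusDef] = []
        columns: list[np.ndarray] = []
        for lineno, rec in enumerate(vf):
            if rec.alts is None or len(rec.alts) != 1:
                raise PanelFormatError(
                    f"{path}: record {rec.id or rec.pos}: exactly one ALT required"
                )
            ref, alt = rec.ref.upper(), rec.alts[0].upper()
            lid = rec.id or f"{rec.chrom}_{rec.pos}"
            lg = None if rec.chrom == "UN" else rec.chrom
            loci.append(LocusDef(lid, (ref, alt), lg))
            col = np.full(len(sample_names), MISSING, dtype=np.int8)
            for i, name in enumerate(sample_names):
                gt = rec.samples[name].get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                if any(a not in (0, 1) for a in gt):
                    raise PanelFormatError(
                        f"{path}: locus {lid!r}: multi-allelic GT {gt} unsupported"
                    )
                col[i] = sum(1 for a in gt if a == 0)  # copies of REF (designated)
            columns.append(col)
    dosages = (
        np.column_stack(columns)
        if columns
        else np.zeros((len(sample_names), 0), dtype=np.int8)
    )
    locate = _location_of(meta, path)
    inds = [(name, locate(name)) for name in sample_names]
    return GenotypePanel(loci, _samples_from_metadata(meta, inds), inds, dosages)


# ------------------------------------------------------------------- public API
def load_panel(
    path: str | Path, format: str, metadata_path: str | Path
) -> GenotypePanel:
    """Load a genotype panel plus its sample-metadata sidecar.

    The designated allele is the first listed allele (VCF REF; for Genepop,
    the lower allele code), recorded in the panel so round-trips are stable.
    """
    path = Path(path)
    if not path.exists():
        raise PanelFormatError(f"{path}: no such file")
    meta = load_metadata(metadata_path)
    if format == "genepop":
        return _parse_genepop(path, meta)
    if format == "vcf":
        return _parse_vcf(path, meta)
    raise ValueError(f"unknown format {format!r} (expected 'genepop' or 'vcf')")


def write_panel(
    panel: GenotypePanel,
    path: str | Path,
    format: str,
    metadata_path: str | Path | None = None,
) -> Path:
    """Write a panel; sample metadata goes to ``<path>.meta.csv`` by default."""
    path = Path(path)
    if format == "genepop":
        _write_genepop(panel, path)
    elif format == "vcf":
        _write_vcf(panel, path)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'genepop' or 'vcf')")
    if metadata_path is None:
        metadata_path = Path(str(path) + ".meta.csv")
    write_metadata(panel, metadata_path)
    return path


# -------------------------------------------------------------------- distances
def load_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    labels = [str(c) for c in df.columns]
    if labels != [str(i) for i in df.index]:
        raise PanelFormatError(f"{path}: row and column labels differ")
    return DistanceMatrix(tuple(labels), df.to_numpy(dtype=float))


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(dm.values, index=list(dm.labels), columns=list(dm.labels)).to_csv(path)
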