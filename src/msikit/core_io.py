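"""Readers and writers for the external formats the toolkit touches.

Covers panel BED files (0-based half-open), per-sample indel VCFs
(1-based), sample manifests, feature tables and the centroid-model JSON,
plus the shared domain types (:class:`MsiLocus`, :class:`IndelCall`,
:class:`SampleManifestEntry`).

Coordinate conventions are converted exactly once, in
:func:`read_indel_vcf`: a VCF record with 1-based position ``pos`` is
assigned to a BED locus ``[start, end)`` when
``start + 1 - padding <= pos <= end + padding``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

log = logging.getLogger(__name__)

# Class labels used throughout.
MSI_H = "MSI-H"
MSI_L = "MSI-L"
MSS = "MSS"
NORMAL = "Normal"
INCONCLUSIVE = "Inconclusive"
UNKNOWN = "unknown"

TRUTH_LABELS = {MSI_H, MSI_L, MSS, NORMAL, UNKNOWN}
MANIFEST_ROLES = {"train", "test", "control-positive", "control-negative", "ntc"}

MODEL_FORMAT_VERSION = "1"


class MsiKitError(Exception):
    """Base class for toolkit errors."""


class ParseError(MsiKitError):
    """A file could not be parsed."""


class ValidationError(MsiKitError):
    """Input violated a documented contract."""


@dataclass(frozen=True)
class MsiLocus:
    """A panel microsatellite target interval.

    ``start``/``end`` are 0-based half-open (BED convention);
    ``feature_index`` fixes the locus's rank in the feature vector.
    """

    chrom: str
    start: int
    end: int
    name: str
    feature_index: int
    repeat_unit: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"locus {self.name!r}: start ({self.start}) must be < end ({self.end})"
            )


@dataclass(frozen=True)
class IndelCall:
    """One indel allele extracted from a VCF record.

    ``length_delta`` is the signed length change len(alt) - len(ref);
    deletions are negative.  ``pos`` is the 1-based VCF position.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    length_delta: int
    locus_name: str | None = None
    filter_status: str = "PASS"
    depth: int | None = None

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValidationError("IndelCall requires nonempty ref and alt")
        expected = len(self.alt) - len(self.ref)
        if self.length_delta != expected:
            raise ValidationError(
                f"length_delta {self.length_delta} != len(alt)-len(ref) = {expected}"
            )
        if self.length_delta == 0:
            raise ValidationError("IndelCall must represent a length change (indel)")


@dataclass
class SampleManifestEntry:
    """One row of a sample manifest: where a sample's VCF lives and what is
    known about it (gold-standard label, role in the study)."""

    sample_id: str
    vcf_path: str
    truth_label: str = UNKNOWN
    role: str = "test"

    def __post_init__(self) -> None:
        if self.truth_label not in TRUTH_LABELS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown truth label {self.truth_label!r}"
            )
        if self.role not in MANIFEST_ROLES:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown role {self.role!r}"
            )


@dataclass
class VcfFilters:
    """Record-level filters applied while extracting indels.

    ``pass_only`` keeps records whose FILTER is PASS or '.'; ``min_depth``
    drops calls below a DP threshold (0 disables); ``locus_padding`` widens
    each locus interval by this many bp on both sides to absorb the
    left-alignment ambiguity of homopolymer indels.
    """

    pass_only: bool = True
    min_depth: int = 0
    locus_padding: int = 2


# ---------------------------------------------------------------------------
# BED panel
# ---------------------------------------------------------------------------

def read_locus_bed(path: str | Path) -> list[MsiLocus]:
    """Read an ordered microsatellite panel from a BED file.

    Columns: chrom, start, end[, name[, repeat_unit]]; 0-based half-open.
    ``feature_index`` is assigned by file order.  Duplicate locus names are
    rejected; unnamed loci get ``chrom:start-end``.
    """
    path = Path(path)
    loci: list[MsiLocus] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] else f"{fields[0]}:{start}-{end}"
            if name in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate locus name {name!r}")
            seen.add(name)
            repeat_unit = fields[4] if len(fields) > 4 and fields[4] not in ("", ".") else None
            loci.append(
                MsiLocus(
                    chrom=fields[0], start=start, end=end, name=name,
                    feature_index=len(loci), repeat_unit=repeat_unit,
                )
            )
    if not loci:
        log.warning("panel BED %s contains no loci", path)
    return loci


def write_locus_bed(loci: Sequence[MsiLocus], path: str | Path) -> None:
    """Write a panel back out as BED (inverse of :func:`read_locus_bed`)."""
    with open(path, "w") as fh:
        for locus in loci:
            cols = [locus.chrom, str(locus.start), str(locus.end), locus.name]
            if locus.repeat_unit:
                cols.append(locus.repeat_unit)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# VCF indel extraction
# ---------------------------------------------------------------------------

def _record_passes_filter(rec: "pysam.VariantRecord", filters: VcfFilters) -> bool:
    if filters.pass_only:
        keys = list(rec.filter.keys())
        if keys and keys != ["PASS"] and keys != ["."]:
            return False
    if filters.min_depth > 0:
        depth = rec.info.get("DP")
        if depth is None or int(depth) < filters.min_depth:
            return False
    return True


def split_indel_alts(rec: "pysam.VariantRecord") -> list[tuple[str, int]]:
    """Split a (possibly multi-allelic) record into ``(alt, length_delta)``
    pairs, keeping only length-changing alleles.

    Symbolic ALTs (``<DEL>`` etc.), breakends and spanning deletions (``*``)
    are skipped — their length change is undefined.
    """
    out: list[tuple[str, int]] = []
    ref = rec.ref or ""
    for alt in rec.alts or ():
        if not alt or alt == "*" or alt.startswith("<") or any(c in alt for c in "[]."):
            continue
        delta = len(alt) - len(ref)
        if delta != 0:
            out.append((alt, delta))
    return out


class LocusCalls(dict):
    """Mapping locus_name -> list[IndelCall] with extraction tallies.

    Every panel locus appears as a key even when it received no calls.
    """

    n_records: int = 0
    n_dropped_outside: int = 0   # indels not assignable to any panel locus
    n_dropped_filtered: int = 0  # indels removed by FILTER/depth filters


def read_indel_vcf(
    path: str | Path,
    loci: Sequence[MsiLocus],
    filters: VcfFilters | None = None,
) -> LocusCalls:
    """Extract indel calls from a VCF and assign them to panel loci.

    Multi-allelic records are split into one :class:`IndelCall` per ALT.
    A call lands on a locus when its 1-based POS is within the padded
    interval ``[start+1-padding, end+padding]``; calls outside every locus
    are dropped and tallied.  Loci with no calls map to an empty list.
    """
    if not loci:
        raise ValidationError("read_indel_vcf requires a nonempty panel")
    filters = filters or VcfFilters()
    pad = filters.locus_padding
    by_chrom: dict[str, list[MsiLocus]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chrom, []).append(locus)

    calls = LocusCalls({locus.name: [] for locus in loci})
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ParseError(f"cannot read VCF {path}: {exc}") from exc
    with vf:
        for rec in vf:
            pairs = split_indel_alts(rec)
            if not pairs:
                continue
            calls.n_records += 1
            if not _record_passes_filter(rec, filters):
                calls.n_dropped_filtered += len(pairs)
                continue
            depth = rec.info.get("DP")
            filter_keys = list(rec.filter.keys())
            filter_status = filter_keys[0] if filter_keys else "PASS"
            target = None
            for locus in by_chrom.get(rec.chrom, ()):  # panels are tiny: linear scan
                if locus.start + 1 - pad <= rec.pos <= locus.end + pad:
                    target = locus
                    break
            if target is None:
                calls.n_dropped_outside += len(pairs)
                continue
            for alt, delta in pairs:
                calls[target.name].append(
                    IndelCall(
                        chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                        length_delta=delta, locus_name=target.name,
                        filter_status=filter_status,
                        depth=int(depth) if depth is not None else None,
                    )
                )
    return calls


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["sample_id", "vcf_path", "truth_label", "role"]


def read_manifest(path: str | Path) -> list[SampleManifestEntry]:
    """Read a sample manifest TSV; relative VCF paths resolve against the
    manifest's own directory."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in ("sample_id", "vcf_path") if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest {path} lacks column(s): {', '.join(missing)}")
    entries: list[SampleManifestEntry] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = row["sample_id"]
        if sid in seen:
            raise ValidationError(f"manifest {path}: duplicate sample_id {sid!r}")
        seen.add(sid)
        vcf = Path(row["vcf_path"])
        if not vcf.is_absolute():
            vcf = path.parent / vcf
        entries.append(
            SampleManifestEntry(
                sample_id=sid,
                vcf_path=str(vcf),
                truth_label=row.get("truth_label", UNKNOWN) or UNKNOWN,
                role=row.get("role", "test") or "test",
            )
        )
    return entries


def write_manifest(entries: Sequence[SampleManifestEntry], path: str | Path) -> None:
    df = pd.DataFrame(
        [[e.sample_id, e.vcf_path, e.truth_label, e.role] for e in entries],
        columns=MANIFEST_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def feature_column_names(loci: Sequence[MsiLocus] | Sequence[str]) -> list[str]:
    """Column names in feature_index order: <name>_npeaks, <name>_meanlen."""
    names = [l.name if isinstance(l, MsiLocus) else l for l in loci]
    cols: list[str] = []
    for name in names:
        cols.extend([f"{name}_npeaks", f"{name}_meanlen"])
    return cols


def write_feature_table(
    sample_ids: Sequence[str],
    loci: Sequence[MsiLocus] | Sequence[str],
    matrix: np.ndarray,
    path: str | Path,
) -> None:
    """Write the n_samples x 2L feature matrix as TSV (lossless round-trip)."""
    matrix = np.asarray(matrix, dtype=float)
    cols = feature_column_names(loci)
    if matrix.shape != (len(sample_ids), len(cols)):
        raise ValidationError(
            f"feature matrix shape {matrix.shape} != ({len(sample_ids)}, {len(cols)})"
        )
    df = pd.DataFrame(matrix, columns=cols)
    df.insert(0, "sample_id", list(sample_ids))
    # repr() of a float round-trips exactly; pandas uses it by default
    df.to_csv(path, sep="\t", index=False)


def read_feature_table(
    path: str | Path,
    loci: Sequence[MsiLocus] | Sequence[str] | None = None,
) -> tuple[list[str], np.ndarray, list[str]]:
    """Read a feature-table TSV; returns (sample_ids, matrix, locus_names).

    When ``loci`` is given the header must contain exactly the expected
    columns in order; a missing column is named in the error.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "sample_id" not in df.columns:
        raise ValidationError(f"feature table {path} lacks 'sample_id' column")
    value_cols = [c for c in df.columns if c != "sample_id"]
    if loci is not None:
        expected = feature_column_names(loci)
        missing = [c for c in expected if c not in value_cols]
        if missing:
            raise ValidationError(
                f"feature table {path} missing column(s): {', '.join(missing)}"
            )
        value_cols = expected
    locus_names = [c[: -len("_npeaks")] for c in value_cols[0::2]]
    return (
        df["sample_id"].astype(str).tolist(),
        df[value_cols].to_numpy(dtype=float),
        locus_names,
    )


# ---------------------------------------------------------------------------
# Model JSON
# ---------------------------------------------------------------------------

def write_model(model, path: str | Path) -> None:
    """Serialize a trained :class:`msikit.classifier.CentroidModel` to JSON."""
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)
        fh.write("\n")


def read_model(path: str | Path):
    """Load a centroid model; refuses unknown format versions."""
    from .classifier import CentroidModel  # local import avoids a cycle

    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"model file {path} is not valid JSON: {exc}") from exc
    version = payload.get("version")
    if version != MODEL_FORMAT_VERSION:
        raise ValidationError(
            f"model file {path}: unsupported format version {version!r} "
            f"(expected {MODEL_FORMAT_VERSION!r})"
        )
    return CentroidModel.from_dict(payload)


# ---------------------------------------------------------------------------
# VCF writing (used by the simulator; deterministic, no timestamps)
# ---------------------------------------------------------------------------

VCF_HEADER_TEMPLATE = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
    '##INFO=<ID=HRUN,Number=1,Type=Integer,Description='
    '"Homopolymer run length adjacent to the variant">\n'
    '##FILTER=<ID=PASS,Description="All filters passed">\n'
)


def write_vcf(
    records: Iterable[tuple[str, int, str, str, int | None, int | None]],
    contigs: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write a minimal, valid, sorted VCF 4.2 file.

    ``records`` are ``(chrom, pos_1based, ref, alts_joined, depth, hrun)``
    tuples; they are sorted by header contig order then position.  The
    header carries no timestamp so identical inputs give identical bytes.
    """
    order = {name: i for i, name in enumerate(contigs)}
    recs = sorted(records, key=lambda r: (order.get(r[0], len(order)), r[1], r[2], r[3]))
    with open(path, "w") as fh:
        fh.write(VCF_HEADER_TEMPLATE)
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alts, depth, hrun in recs:
            info_parts = []
            if depth is not None:
                info_parts.append(f"DP={depth}")
            if hrun is not None:
                info_parts.append(f"HRUN={hrun}")
            info = ";".join(info_parts) or "."
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alts}\t.\tPASS\t{info}\n")
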