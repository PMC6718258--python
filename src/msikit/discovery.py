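"""Marker discovery: which homopolymer indels discriminate MSI-H tumors.

Given exome-scale indel VCFs from a labeled cohort (MSI-H positives;
MSI-L and MSS together forming the negatives), every unique indel —
keyed by (chrom, pos, ref, alt, homopolymer repeat number) — is tested
for association with MSI status by a two-sided Fisher's exact test on
carrier counts.  Candidates then pass a stringent filter: p < 1e-4,
carried by >= 80% of MSI-H cases, absent from MSS cases, and an ALT
allele 5-7 bp long.  Markers surviving the filter are the loci worth
placing on a targeted MSI panel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import pysam
from scipy import stats

from .core_io import (
    MSI_H,
    MSI_L,
    MSS,
    ParseError,
    SampleManifestEntry,
    ValidationError,
    VcfFilters,
    _record_passes_filter,
    split_indel_alts,
)

log = logging.getLogger(__name__)

IndelKey = tuple[str, int, str, str, int]


@dataclass
class CandidateIndel:
    """One unique indel with its carrier counts across the labeled cohort."""

    chrom: str
    pos: int
    ref: str
    alt: str
    repeat_number: int
    carriers_pos: int = 0
    carriers_neg: int = 0
    carriers_mss: int = 0
    p_value: float | None = None

    @property
    def key(self) -> IndelKey:
        return (self.chrom, self.pos, self.ref, self.alt, self.repeat_number)

    @property
    def alt_length(self) -> int:
        return len(self.alt)


@dataclass
class IndelCatalog:
    """All unique indels seen across the cohort plus the group sizes."""

    candidates: list[CandidateIndel]
    n_pos: int
    n_neg: int
    n_mss: int


def homopolymer_run_length(seq: str, start: int = 0) -> int:
    """Length of the maximal single-base run starting at ``start`` (0-based)."""
    if start >= len(seq) or not seq:
        return 0
    base = seq[start].upper()
    run = 0
    for ch in seq[start:]:
        if ch.upper() != base:
            break
        run += 1
    return run


def _repeat_number(
    rec: "pysam.VariantRecord", reference=None
) -> int:
    """Homopolymer repeat number for a record: from the reference if
    available (run starting at pos+1), else the HRUN INFO tag, else 0."""
    if reference is not None:
        try:
            chrom_seq = reference[rec.chrom]
        except KeyError:
            return 0
        # rec.pos is 1-based anchor; the run starts at the next base
        window = str(chrom_seq[rec.pos : rec.pos + 100])
        return homopolymer_run_length(window)
    try:
        hrun = rec.info.get("HRUN")
    except (KeyError, ValueError):  # tag absent from the header entirely
        hrun = None
    if hrun is not None:
        return int(hrun)
    return 0


def catalog_indels(
    manifest: Sequence[SampleManifestEntry],
    reference: str | Path | None = None,
    filters: VcfFilters | None = None,
) -> IndelCatalog:
    """Catalog unique indels across a labeled cohort and count carriers.

    Positives are MSI-H samples; negatives are MSI-L and MSS combined.
    A sample carries a candidate when its VCF contains that exact
    (chrom, pos, ref, alt, repeat number) key.
    """
    filters = filters or VcfFilters()
    fasta = None
    if reference is not None:
        from pyfaidx import Fasta

        fasta = Fasta(str(reference))

    pos_ids, neg_ids, mss_ids = set(), set(), set()
    for entry in manifest:
        if entry.truth_label == MSI_H:
            pos_ids.add(entry.sample_id)
        elif entry.truth_label in (MSI_L, MSS):
            neg_ids.add(entry.sample_id)
            if entry.truth_label == MSS:
                mss_ids.add(entry.sample_id)
        else:
            raise ValidationError(
                f"sample {entry.sample_id!r} has label {entry.truth_label!r}; "
                f"discovery needs {MSI_H}, {MSI_L} or {MSS}"
            )
    if not pos_ids or not neg_ids:
        raise ValidationError(
            f"discovery needs at least one positive ({MSI_H}) and one negative "
            f"({MSI_L}/{MSS}) sample"
        )

    candidates: dict[IndelKey, CandidateIndel] = {}
    for entry in manifest:
        seen: set[IndelKey] = set()
        try:
            vf = pysam.VariantFile(entry.vcf_path)
        except (OSError, ValueError) as exc:
            raise ParseError(f"cannot read VCF {entry.vcf_path}: {exc}") from exc
        with vf:
            for rec in vf:
                pairs = split_indel_alts(rec)
                if not pairs or not _record_passes_filter(rec, filters):
                    continue
                repeat_n = _repeat_number(rec, fasta)
                for alt, _delta in pairs:
                    seen.add((rec.chrom, rec.pos, rec.ref, alt, repeat_n))
        for key in seen:
            cand = candidates.get(key)
            if cand is None:
                cand = candidates[key] = CandidateIndel(*key)
            if entry.sample_id in pos_ids:
                cand.carriers_pos += 1
            else:
                cand.carriers_neg += 1
                if entry.sample_id in mss_ids:
                    cand.carriers_mss += 1

    out = sorted(candidates.values(), key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    n_pos, n_neg = len(pos_ids), len(neg_ids)
    for cand in out:
        cand.p_value = fisher_exact_two_sided(
            cand.carriers_pos,
            n_pos - cand.carriers_pos,
            cand.carriers_neg,
            n_neg - cand.carriers_neg,
        )
    log.info(
        "cataloged %d unique indels across %d samples (%d positive, %d negative)",
        len(out), len(manifest), n_pos, n_neg,
    )
    return IndelCatalog(out, n_pos=n_pos, n_neg=n_neg, n_mss=len(mss_ids))


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    The p-value sums hypergeometric probabilities of all tables with the
    same margins whose probability does not exceed the observed table's.
    """
    cells = (a, b, c, d)
    for v in cells:
        if not isinstance(v, (int,)) or isinstance(v, bool):
            raise ValidationError(f"Fisher cell counts must be integers, got {cells}")
        if v < 0:
            raise ValidationError(f"Fisher cell counts must be nonnegative, got {cells}")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


def select_markers(
    catalog: IndelCatalog,
    p_max: float = 1e-4,
    min_pos_fraction: float = 0.8,
    max_mss_carriers: int = 0,
    alt_len_range: tuple[int, int] = (5, 7),
) -> list[CandidateIndel]:
    """Apply the stringent marker filter and rank survivors.

    Keeps candidates with p < ``p_max``, carried by at least
    ceil(min_pos_fraction * n_pos) MSI-H cases, at most
    ``max_mss_carriers`` MSS carriers, and ALT string length within
    ``alt_len_range`` (inclusive).  Sorted ascending by p, ties broken by
    (chrom, pos).
    """
    lo, hi = alt_len_range
    min_pos = math.ceil(min_pos_fraction * catalog.n_pos)
    kept = [
        c
        for c in catalog.candidates
        if c.p_value is not None
        and c.p_value < p_max
        and c.carriers_pos >= min_pos
        and c.carriers_mss <= max_mss_carriers
        and lo <= c.alt_length <= hi
    ]
    kept.sort(key=lambda c: (c.p_value, c.chrom, c.pos))
    log.info("marker filter retained %d of %d candidates", len(kept), len(catalog.candidates))
    return kept


MARKER_COLUMNS = [
    "chrom", "pos", "ref", "alt", "repeat_n",
    "carriers_pos", "carriers_neg", "carriers_mss", "p_value",
]


def write_marker_table(markers: Sequence[CandidateIndel], path: str | Path) -> None:
    """Write selected markers as a TSV (1-based positions, as in the VCF)."""
    df = pd.DataFrame(
        [
            [m.chrom, m.pos, m.ref, m.alt, m.repeat_number,
             m.carriers_pos, m.carriers_neg, m.carriers_mss, m.p_value]
            for m in markers
        ],
        columns=MARKER_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def markers_to_bed(markers: Sequence[CandidateIndel], path: str | Path) -> None:
    """Derive a BED of marker intervals covering each indel's REF span."""
    with open(path, "w") as fh:
        for m in markers:
            start = m.pos - 1
            end = start + max(len(m.ref), 1)
            fh.write(f"{m.chrom}\t{start}\t{end}\t{m.chrom}:{m.pos}:{m.ref}>{m.alt}\n")
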