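"""Seeded synthetic data: panel cohorts, dilution series, WES catalogs.

The generator emulates, at the indel-allele level, the signal the caller
consumes:

* **MSI-H tumors** show many distinct indel allele lengths (peaks) at a
  large fraction of panel loci, with deletion-shifted means — the
  signature of replication slippage under mismatch-repair deficiency.
  A per-sample severity factor widens the MSI-H cloud, mirroring the
  broad spread of real MSI-H cases that the model's two MSI-H clusters
  capture.
* **MSS and normal samples** show rare, short (−1 bp) stutter alleles.
* **Dilution series** mix an MSI-H allele set into an MSS background,
  retaining each MSI-H-specific allele with probability f / f_detect —
  a detection-probability analog of the limit-of-detection experiment.
* **WES-like catalogs** plant MSI-discriminative homopolymer markers
  (ALT length 5–7 bp, carried by ≥80% of MSI-H cases, absent in MSS)
  among label-independent background indels, for exercising marker
  discovery end to end.

All randomness flows from one top-level seed through
``numpy.random.SeedSequence`` spawning, so each sample's stream is
independent and every output is byte-identical under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core_io import (
    MSI_H,
    MSI_L,
    MSS,
    NORMAL,
    IndelCall,
    MsiLocus,
    SampleManifestEntry,
    ValidationError,
    write_locus_bed,
    write_manifest,
    write_vcf,
)

log = logging.getLogger(__name__)


@dataclass
class SimParams:
    """Per-class locus models for the synthetic cohorts.

    MSS/Normal loci produce at most one stutter allele (drawn from
    ``mss_deltas``) at rate ``mss_peak_rate``; MSI-H loci are unstable
    with probability ``msih_fraction_unstable`` and then carry a
    truncated-Poisson (>= 1) number of distinct alleles at rate
    ``msih_peak_rate``, with signed lengths near ``msih_delta_mean`` bp.
    ``msih_severity_range`` scales both the rate and the mean per sample,
    spreading the MSI-H group. ``detect_floor`` is the MSI-H fraction at
    which dilution retention saturates.
    """

    n_loci: int = 29
    mss_peak_rate: float = 0.4          # lambda_S: mean distinct alleles per locus
    mss_deltas: tuple[int, ...] = (-1,)
    msih_peak_rate: float = 3.0         # lambda_H
    msih_fraction_unstable: float = 0.8
    msih_delta_mean: float = -4.0       # bp, deletions negative
    msih_delta_sd: float = 1.5
    msih_severity_range: tuple[float, float] = (0.6, 1.4)
    depth: int = 500                    # constant DP INFO value
    detect_floor: float = 0.025
    seed: int = 17

    def __post_init__(self) -> None:
        if not self.mss_peak_rate < self.msih_peak_rate:
            raise ValidationError("MSS peak rate must be below the MSI-H peak rate")
        if not (0 < self.msih_fraction_unstable <= 1):
            raise ValidationError("msih_fraction_unstable must be in (0, 1]")
        if self.n_loci < 1:
            raise ValidationError("n_loci must be positive")


def default_panel(n_loci: int = 29) -> list[MsiLocus]:
    """A synthetic homopolymer panel; the first two loci carry the shared
    Bethesda marker names (BAT-25, BAT-26) at their hg19 coordinates."""
    named = [
        ("chr4", 55598211, 55598236, "BAT-25", "T"),
        ("chr2", 47641559, 47641586, "BAT-26", "A"),
    ]
    loci: list[MsiLocus] = []
    for i in range(n_loci):
        if i < len(named):
            chrom, start, end, name, unit = named[i]
        else:
            chrom = f"chr{(i % 21) + 1}"
            start = 10_000_000 + 50_000 * i
            end = start + 20
            name, unit = f"HP-{i + 1:02d}", "A"
        loci.append(MsiLocus(chrom, start, end, name, feature_index=i, repeat_unit=unit))
    return loci


def _panel_contigs(loci: Sequence[MsiLocus]) -> dict[str, int]:
    def chrom_rank(name: str) -> tuple[int, str]:
        tail = name.removeprefix("chr")
        return (int(tail), "") if tail.isdigit() else (99, tail)

    contigs: dict[str, int] = {}
    for locus in sorted(loci, key=lambda l: chrom_rank(l.chrom)):
        contigs[locus.chrom] = max(contigs.get(locus.chrom, 0), locus.end + 10_000)
    return contigs


def _distinct_deltas(rng: np.random.Generator, n: int, mean: float, sd: float) -> list[int]:
    """Draw ``n`` distinct nonzero signed lengths near N(mean, sd)."""
    out: set[int] = set()
    attempts = 0
    while len(out) < n and attempts < 60 * n:
        delta = int(round(rng.normal(mean, sd)))
        attempts += 1
        if delta != 0:
            out.add(delta)
    return sorted(out)


def sample_locus_deltas(
    rng: np.random.Generator, params: SimParams, label: str
) -> list[list[int]]:
    """Distinct indel length_deltas per panel locus for one sample."""
    per_locus: list[list[int]] = []
    if label == MSI_H:
        lo, hi = params.msih_severity_range
        severity = rng.uniform(lo, hi)
        rate = params.msih_peak_rate * severity
        mean = params.msih_delta_mean * severity
        for _ in range(params.n_loci):
            if rng.random() < params.msih_fraction_unstable:
                n = max(1, int(rng.poisson(rate)))  # truncated at >= 1
                per_locus.append(_distinct_deltas(rng, n, mean, params.msih_delta_sd))
            else:
                n = min(int(rng.poisson(params.mss_peak_rate)), len(params.mss_deltas))
                per_locus.append(sorted(rng.choice(params.mss_deltas, n, replace=False)))
    elif label in (MSS, NORMAL):
        for _ in range(params.n_loci):
            n = min(int(rng.poisson(params.mss_peak_rate)), len(params.mss_deltas))
            per_locus.append(sorted(int(d) for d in rng.choice(params.mss_deltas, n, replace=False)))
    else:
        raise ValidationError(f"no locus model for label {label!r}")
    return per_locus


def _locus_records(
    locus: MsiLocus, deltas: Sequence[int], depth: int
) -> list[tuple[str, int, str, str, int | None, int | None]]:
    """Encode a locus's distinct deltas as at most two VCF records.

    Deletions share one multi-allelic record anchored at the locus start
    (REF spans the largest deletion); insertions share a second record.
    Using a run of the locus's repeat base keeps the records homopolymer-
    realistic and exercises multi-allelic splitting downstream.
    """
    base = (locus.repeat_unit or "A")[0]
    pos = locus.start + 1  # 1-based anchor inside [start+1, end]
    dels = sorted((d for d in deltas if d < 0), reverse=True)
    ins = sorted(d for d in deltas if d > 0)
    hrun = locus.end - locus.start
    records = []
    if dels:
        max_del = -min(dels)
        ref = base * (1 + max_del)
        alts = ",".join(base * (1 + max_del + d) for d in dels)
        records.append((locus.chrom, pos, ref, alts, depth, hrun))
    if ins:
        alts = ",".join(base * (1 + d) for d in ins)
        records.append((locus.chrom, pos, base, alts, depth, hrun))
    return records


def _write_sample_vcf(
    path: Path,
    loci: Sequence[MsiLocus],
    per_locus_deltas: Sequence[Sequence[int]],
    contigs: Mapping[str, int],
    depth: int,
) -> None:
    records = []
    for locus, deltas in zip(loci, per_locus_deltas):
        records.extend(_locus_records(locus, deltas, depth))
    write_vcf(records, contigs, path)


@dataclass
class CohortSim:
    """Paths and truth for one simulated cohort."""

    out_dir: Path
    loci: list[MsiLocus]
    bed_path: Path
    manifest_path: Path
    truth_path: Path
    entries: list[SampleManifestEntry]
    truth: dict[str, str]

    def vcf_path(self, sample_id: str) -> Path:
        return self.out_dir / f"{sample_id}.vcf"


def cohort_feature_matrix(sim: CohortSim, filters=None):
    """Convenience: extract the feature matrix of a simulated cohort."""
    from .core_io import read_indel_vcf
    from .features import build_feature_matrix

    cohort = {
        e.sample_id: read_indel_vcf(sim.vcf_path(e.sample_id), sim.loci, filters)
        for e in sim.entries
    }
    return build_feature_matrix(cohort, sim.loci)


def simulate_cohort(
    params: SimParams,
    n_msih: int = 22,
    n_mss: int = 25,
    n_normal: int = 47,
    out_dir: str | Path = ".",
    seed: int | None = None,
) -> CohortSim:
    """Generate a labeled panel cohort: one VCF per sample plus manifest,
    truth table, panel BED and a params echo.  Deterministic under seed."""
    if min(n_msih, n_mss, n_normal) < 0:
        raise ValidationError("cohort counts must be nonnegative")
    seed = params.seed if seed is None else seed
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    loci = default_panel(params.n_loci)
    contigs = _panel_contigs(loci)

    plan = (
        [(f"MSIH-{i + 1:03d}", MSI_H) for i in range(n_msih)]
        + [(f"MSS-{i + 1:03d}", MSS) for i in range(n_mss)]
        + [(f"NORM-{i + 1:03d}", NORMAL) for i in range(n_normal)]
    )
    streams = np.random.SeedSequence(seed).spawn(len(plan))
    entries: list[SampleManifestEntry] = []
    truth: dict[str, str] = {}
    for (sid, label), stream in zip(plan, streams):
        rng = np.random.default_rng(stream)
        vcf_path = out_dir / f"{sid}.vcf"
        _write_sample_vcf(
            vcf_path, loci, sample_locus_deltas(rng, params, label), contigs, params.depth
        )
        entries.append(SampleManifestEntry(sid, vcf_path.name, truth_label=label, role="train"))
        truth[sid] = label

    bed_path = out_dir / "panel.bed"
    write_locus_bed(loci, bed_path)
    manifest_path = out_dir / "manifest.tsv"
    write_manifest(entries, manifest_path)
    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("sample_id\ttruth_label\n")
        for sid, label in truth.items():
            fh.write(f"{sid}\t{label}\n")
    with open(out_dir / "params.json", "w") as fh:
        json.dump({"seed": seed, **asdict(params)}, fh, indent=1)
        fh.write("\n")
    log.info("simulated cohort of %d samples under %s (seed %d)", len(plan), out_dir, seed)
    return CohortSim(out_dir, loci, bed_path, manifest_path, truth_path, entries, truth)


def simulate_dilution_series(
    msih_calls: Mapping[str, Sequence[IndelCall]],
    mss_calls: Mapping[str, Sequence[IndelCall]],
    fractions: Sequence[float],
    params: SimParams,
    loci: Sequence[MsiLocus],
    out_dir: str | Path,
    seed: int | None = None,
) -> list[tuple[float, Path]]:
    """Mix an MSI-H sample into an MSS background at given fractions.

    At fraction ``f`` each MSI-H-specific allele (a (locus, length_delta)
    pair absent from the MSS sample) is retained independently with
    probability min(1, f / detect_floor); MSS alleles are always kept.
    Returns (fraction, vcf_path) pairs in input order.
    """
    for f in fractions:
        if not (0 <= f <= 1):
            raise ValidationError(f"dilution fraction {f} outside [0, 1]")
    seed = params.seed if seed is None else seed
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    contigs = _panel_contigs(loci)
    locus_order = sorted(loci, key=lambda l: l.feature_index)

    mss_sets = {l.name: {c.length_delta for c in mss_calls.get(l.name, ())} for l in locus_order}
    msih_specific = {
        l.name: sorted(
            {c.length_delta for c in msih_calls.get(l.name, ())} - mss_sets[l.name]
        )
        for l in locus_order
    }

    streams = np.random.SeedSequence(seed).spawn(len(fractions))
    outputs: list[tuple[float, Path]] = []
    for f, stream in zip(fractions, streams):
        rng = np.random.default_rng(stream)
        p_keep = min(1.0, f / params.detect_floor)
        per_locus: list[list[int]] = []
        for locus in locus_order:
            kept = [d for d in msih_specific[locus.name] if rng.random() < p_keep]
            per_locus.append(sorted(set(kept) | mss_sets[locus.name]))
        path = out_dir / f"dilution_f{f:.6f}.vcf"
        _write_sample_vcf(path, locus_order, per_locus, contigs, params.depth)
        outputs.append((f, path))
    return outputs


@dataclass
class WesSim:
    """A labeled WES-like cohort with a planted-marker truth table."""

    out_dir: Path
    manifest_path: Path
    truth_path: Path
    entries: list[SampleManifestEntry]
    planted: list[tuple[str, int, str, str, int]]  # (chrom, pos, ref, alt, hrun)


def simulate_wes_catalog(
    out_dir: str | Path,
    n_msih: int = 7,
    n_msil: int = 7,
    n_mss: int = 14,
    n_markers: int = 12,
    n_background: int = 500,
    background_carrier_rate: float = 0.15,
    seed: int = 7,
) -> WesSim:
    """Plant MSI-discriminative homopolymer markers in a WES-like cohort.

    Planted markers are homopolymer insertions with ALT length uniform in
    {5, 6, 7}, carried by 6 or 7 of the MSI-H cases and by no MSI-L or
    MSS case.  Background indels (mixed insertions/deletions, ALT lengths
    1-10) are carried at a label-independent rate.  Each sample's VCF and
    a truth table of planted keys are written under ``out_dir``.
    """
    if min(n_msih, n_msil, n_mss) < 1:
        raise ValidationError("WES cohort needs at least one sample per label")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    sample_plan = (
        [(f"WES-MSIH-{i + 1:02d}", MSI_H) for i in range(n_msih)]
        + [(f"WES-MSIL-{i + 1:02d}", MSI_L) for i in range(n_msil)]
        + [(f"WES-MSS-{i + 1:02d}", MSS) for i in range(n_mss)]
    )
    n_samples = len(sample_plan)
    contigs = {f"chr{c}": 250_000_000 for c in range(1, 22)}

    used: set[tuple[str, int]] = set()

    def fresh_site() -> tuple[str, int]:
        while True:
            chrom = f"chr{int(rng.integers(1, 22))}"
            pos = int(rng.integers(100_000, 200_000_000))
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                return chrom, pos

    planted: list[tuple[str, int, str, str, int]] = []
    carriers: dict[tuple[str, int, str, str, int], set[int]] = {}
    msih_idx = [i for i, (_, lab) in enumerate(sample_plan) if lab == MSI_H]
    for _ in range(n_markers):
        chrom, pos = fresh_site()
        alt_len = int(rng.integers(5, 8))
        ref, alt = "A", "A" * alt_len
        hrun = int(rng.integers(8, 16))
        key = (chrom, pos, ref, alt, hrun)
        n_carry = int(rng.integers(6, 8)) if n_msih == 7 else n_msih
        n_carry = min(n_carry, n_msih)
        carry = rng.choice(msih_idx, size=n_carry, replace=False)
        planted.append(key)
        carriers[key] = set(int(i) for i in carry)

    for _ in range(n_background):
        chrom, pos = fresh_site()
        if rng.random() < 0.5:
            d = int(rng.integers(1, 7))
            ref, alt = "A" * (1 + d), "A"
        else:
            alt_len = int(rng.integers(2, 11))
            ref, alt = "A", "A" * alt_len
        hrun = int(rng.integers(1, 16))
        key = (chrom, pos, ref, alt, hrun)
        mask = rng.random(n_samples) < background_carrier_rate
        carriers[key] = set(int(i) for i in np.flatnonzero(mask))

    entries: list[SampleManifestEntry] = []
    for i, (sid, label) in enumerate(sample_plan):
        records = [
            (chrom, pos, ref, alt, 200, hrun)
            for (chrom, pos, ref, alt, hrun), who in carriers.items()
            if i in who
        ]
        path = out_dir / f"{sid}.vcf"
        write_vcf(records, contigs, path)
        entries.append(SampleManifestEntry(sid, path.name, truth_label=label, role="train"))

    manifest_path = out_dir / "manifest.tsv"
    write_manifest(entries, manifest_path)
    truth_path = out_dir / "planted_markers.tsv"
    with open(truth_path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\trepeat_n\n")
        for chrom, pos, ref, alt, hrun in sorted(planted):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{hrun}\n")
    log.info(
        "simulated WES catalog: %d samples, %d planted markers, %d background indels",
        n_samples, n_markers, n_background,
    )
    return WesSim(out_dir, manifest_path, truth_path, entries, planted)
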