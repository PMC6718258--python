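"""Marker discovery on a WES-like cohort: catalog every unique indel across
labeled samples, test MSI association by Fisher's exact test and apply the
stringent panel-selection filter.

Run:  python examples/marker_discovery.py
"""

import tempfile

from msikit import catalog_indels, read_manifest, select_markers, simulate_wes_catalog

with tempfile.TemporaryDirectory() as tmp:
    # 7 MSI-H, 7 MSI-L and 14 MSS exomes with 12 planted discriminative
    # homopolymer markers among 500 label-independent background indels.
    wes = simulate_wes_catalog(tmp, seed=7)

    catalog = catalog_indels(read_manifest(wes.manifest_path))
    print(f"cataloged {len(catalog.candidates)} unique indels "
          f"({catalog.n_pos} MSI-H vs {catalog.n_neg} MSI-L/MSS samples)")

    markers = select_markers(catalog)  # p < 1e-4, >=80% MSI-H, 0 MSS, ALT 5-7 bp
    print(f"{len(markers)} markers pass the filter "
          f"(planted truth: {len(wes.planted)})")
    for m in markers[:5]:
        print(f"  {m.chrom}:{m.pos} {m.ref}>{m.alt} repeat={m.repeat_number} "
              f"carriers {m.carriers_pos}/{catalog.n_pos} MSI-H, "
              f"{m.carriers_mss} MSS, p={m.p_value:.2e}")

    recovered = {m.key for m in markers} == set(wes.planted)
    print(f"exact recovery of the planted marker set: {recovered}")

# Each surviving marker is carried by nearly every MSI-H exome and by no
# MSS exome, with an association p-value far below 1e-4 — the profile of a
# locus worth placing on a targeted MSI panel.
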