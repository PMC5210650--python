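"""Deterministic selection of carrier samples for the read-support display.

Only carriers with read depth >= 10 and genotype quality >= 20 qualify; when
a genotype class (het/hom) has more than five qualifying carriers, the five
with the highest GQ are kept (ties broken by ascending sample id so the
selection is reproducible).  The module emits a processing manifest — the
reassembly step that would produce the small per-variant BAMs is recorded as
opaque parameters, not run.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

from .model import GenomeInterval, ReadVizManifest, ReadVizSample, Variant

DEFAULT_MIN_DP = 10
DEFAULT_MIN_GQ = 20
DEFAULT_MAX_PER_CLASS = 5
DEFAULT_WINDOW_WIDTH = 125

#: Parameters of the external reassembly step, recorded in every manifest so
#: a downstream caller can reproduce the original read extraction.
REASSEMBLY_PARAMETERS = {
    "padding_around_snps": 300,
    "padding_around_indels": 300,
    "max_alternate_alleles": 3,
    "max_num_haplotypes_in_population": 200,
    "min_pruning": 3,
}

GENOTYPE_CLASSES = ("het", "hom")

MANIFEST_COLUMNS = [
    "variant_key", "sample_id", "genotype_class", "gq", "dp",
    "window_chrom", "window_start", "window_end", "read_group", "batch_id",
]


def select_samples(
    carriers: Iterable[ReadVizSample],
    min_dp: int = DEFAULT_MIN_DP,
    min_gq: int = DEFAULT_MIN_GQ,
    max_per_class: int = DEFAULT_MAX_PER_CLASS,
) -> dict[str, list[ReadVizSample]]:
    """Per-genotype-class top-GQ selection of qualifying carriers.

    Returns ``{"het": [...], "hom": [...]}`` with each list sorted by
    descending GQ (ascending sample id on ties) and capped at
    ``max_per_class`` entries.
    """
    selection: dict[str, list[ReadVizSample]] = {c: [] for c in GENOTYPE_CLASSES}
    for sample in carriers:
        if sample.genotype_class not in selection:
            raise ValueError(f"unknown genotype class {sample.genotype_class!r}")
        if sample.dp >= min_dp and sample.gq >= min_gq:
            selection[sample.genotype_class].append(sample)
    for cls in selection:
        selection[cls].sort(key=lambda s: (-s.gq, s.sample_id))
        selection[cls] = selection[cls][:max_per_class]
    return selection


def display_window(
    chrom: str,
    pos: int,
    window_width: int = DEFAULT_WINDOW_WIDTH,
) -> GenomeInterval:
    """Window of ``window_width`` bases centered on the variant's first ref base.

    The left flank is floor((w-1)/2) bases, the right flank the remainder;
    ``pos`` is 1-based, the window 0-based half-open.
    """
    if window_width < 1:
        raise ValueError("window_width must be >= 1")
    center0 = pos - 1
    left = (window_width - 1) // 2
    start = max(0, center0 - left)
    return GenomeInterval(chrom, start, start + window_width)


def build_manifest(
    variant: Variant,
    selection: dict[str, list[ReadVizSample]],
    window_width: int = DEFAULT_WINDOW_WIDTH,
) -> ReadVizManifest:
    """Assemble the manifest for one variant from a per-class selection."""
    selected = [s for cls in GENOTYPE_CLASSES for s in selection.get(cls, [])]
    return ReadVizManifest(
        variant_key=variant.key,
        selected=selected,
        window=display_window(variant.chrom, variant.pos, window_width),
        parameters=dict(REASSEMBLY_PARAMETERS),
    )


def read_group_label(variant_key: str, sample: ReadVizSample) -> str:
    """Unique per-(variant, sample) read-group label."""
    return f"{variant_key}_{sample.sample_id}_{sample.genotype_class}"


def batch_manifests(
    manifests: Sequence[ReadVizManifest],
    batch_size: int,
) -> list[list[tuple[ReadVizManifest, dict[str, str]]]]:
    """Partition manifests in input order into batches of ``batch_size``.

    Each entry carries a ``(sample_id, genotype_class) -> read_group`` map;
    labels are unique across the whole run because the variant key
    participates in the label.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    batches: list[list[tuple[ReadVizManifest, dict[tuple[str, str], str]]]] = []
    for i in range(0, len(manifests), batch_size):
        batch = []
        for manifest in manifests[i:i + batch_size]:
            labels = {
                (s.sample_id, s.genotype_class):
                    read_group_label(manifest.variant_key, s)
                for s in manifest.selected
            }
            batch.append((manifest, labels))
        batches.append(batch)
    return batches


def write_manifest_tsv(
    batches: list[list[tuple[ReadVizManifest, dict[str, str]]]],
    path: str | Path,
) -> int:
    """Write the batched manifests as a TSV; returns the number of rows."""
    n = 0
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(MANIFEST_COLUMNS)
        for batch_id, batch in enumerate(batches):
            for manifest, labels in batch:
                for s in manifest.selected:
                    writer.writerow([
                        manifest.variant_key, s.sample_id, s.genotype_class,
                        s.gq, s.dp, manifest.window.chrom,
                        manifest.window.start, manifest.window.end,
                        labels[(s.sample_id, s.genotype_class)], batch_id,
                    ])
                    n += 1
    return n
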