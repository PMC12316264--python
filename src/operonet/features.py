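"""Turn a gene pair plus coverage tracks into a fixed-shape signal tensor.

For each pair the per-base depths over gene 1, the intergenic region (IGR)
and gene 2 are concatenated, proportionally resampled to 150 positions,
min-max scaled to [0, 1] per sample, and split into three masked channels
(one per region).  Up to six samples are stacked as rows, giving a tensor
of shape ``(150, 6, 3)`` per pair — positions x sample rows x channels.

The three region channels are disjoint: channel c is zero at every position
allocated to another region, and a pair without an IGR has an all-zero IGR
channel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome_io import CoverageTrack, GenePair

TENSOR_LENGTH = 150
TENSOR_ROWS = 6
TENSOR_CHANNELS = 3

DATASET_FORMAT_VERSION = 1


class DatasetIntegrityError(RuntimeError):
    """Archive and manifest disagree, or the archive is unreadable."""


@dataclass
class PairSignal:
    """Raw per-base depths for one pair, per sample, in transcript order."""

    pair_id: str
    sample_ids: list[str]
    gene1: list[np.ndarray]  # one vector per sample
    igr: list[np.ndarray]
    gene2: list[np.ndarray]


@dataclass
class FeatureTensor:
    pair_id: str
    values: np.ndarray  # (150, 6, 3) float32 in [0, 1]
    boundaries: tuple[int, int, int]  # positions allocated to gene1/igr/gene2


def extract_pair_signal(
    pair: GenePair,
    tracks: Sequence[CoverageTrack],
    reorient_minus: bool = True,
) -> PairSignal:
    """Slice per-base depths for gene1 / IGR / gene2 from each track.

    For minus-strand pairs (with ``reorient_minus``, the default) the three
    segments are taken in transcription order — the genomic-rightmost gene
    first — and each segment is reversed, so the position axis always runs
    5'->3' along the transcript and "gene 1" is the upstream gene.
    """
    if not tracks:
        raise ValueError("at least one coverage track is required")
    gene1_vecs, igr_vecs, gene2_vecs = [], [], []
    for track in tracks:
        g1 = track.slice(pair.seqid, pair.gene1.start, pair.gene1.end)
        igr = track.slice(pair.seqid, pair.igr_start, pair.igr_end)
        g2 = track.slice(pair.seqid, pair.gene2.start, pair.gene2.end)
        if pair.strand == "-" and reorient_minus:
            g1, g2 = g2[::-1], g1[::-1]
            igr = igr[::-1]
        gene1_vecs.append(np.asarray(g1))
        igr_vecs.append(np.asarray(igr))
        gene2_vecs.append(np.asarray(g2))
    return PairSignal(
        pair_id=pair.pair_id,
        sample_ids=[t.sample_id for t in tracks],
        gene1=gene1_vecs,
        igr=igr_vecs,
        gene2=gene2_vecs,
    )


def allocate_positions(
    len1: int, lenI: int, len2: int, total: int = TENSOR_LENGTH
) -> tuple[int, int, int]:
    """Apportion ``total`` positions to the three segments.

    Largest-remainder apportionment proportional to segment lengths, with
    the guarantee that every nonempty segment receives at least one
    position.  An empty IGR receives exactly zero.
    """
    if len1 < 1 or len2 < 1 or lenI < 0:
        raise ValueError("gene lengths must be >= 1 and IGR length >= 0")
    lengths = np.array([len1, lenI, len2], dtype=float)
    nonempty = lengths > 0
    if total < int(nonempty.sum()):
        raise ValueError(
            f"total={total} too small for {int(nonempty.sum())} nonempty segments"
        )
    quotas = total * lengths / lengths.sum()
    alloc = np.floor(quotas).astype(int)
    remainder = total - alloc.sum()
    # Distribute leftovers by descending fractional part; ties by index.
    fracs = quotas - np.floor(quotas)
    order = sorted(range(3), key=lambda i: (-fracs[i], i))
    for i in order[:remainder]:
        alloc[i] += 1
    # >=1 guarantee for nonempty segments: borrow from the largest.
    for i in range(3):
        while nonempty[i] and alloc[i] == 0:
            donor = int(np.argmax(alloc))
            alloc[donor] -= 1
            alloc[i] += 1
    return int(alloc[0]), int(alloc[1]), int(alloc[2])


def resample_segment(depths: np.ndarray, n: int) -> np.ndarray:
    """Resample a per-base depth vector to ``n`` positions.

    Area-preserving binning: output position j is the mean of the input
    over the real interval [jL/n, (j+1)L/n), with partially covered bases
    weighted by their fractional overlap.  A constant input maps to the
    same constant, and L == n returns the input unchanged.
    """
    depths = np.asarray(depths, dtype=float)
    L = depths.shape[0]
    if n < 1:
        raise ValueError("n must be >= 1")
    if L == 0:
        raise ValueError("cannot resample an empty segment; allocate 0 positions")
    if L == n:
        return depths.copy()
    # C(t) = integral of the step function over [0, t]
    csum = np.concatenate([[0.0], np.cumsum(depths)])

    def integral(t: np.ndarray) -> np.ndarray:
        t = np.clip(t, 0.0, float(L))
        base = np.floor(t).astype(int)
        frac = t - base
        base = np.minimum(base, L - 1)
        return csum[base] + frac_adjust(t, base, frac)

    def frac_adjust(t, base, frac):
        # at t == L, floor(t) was clamped; integral is total sum exactly
        out = frac * depths[base]
        at_end = t >= L
        out = np.where(at_end, csum[L] - csum[base], out)
        return out

    edges = np.arange(n + 1) * (L / n)
    cum = integral(edges)
    return (cum[1:] - cum[:-1]) / (L / n)


def _minmax_scale(vec: np.ndarray) -> np.ndarray:
    lo, hi = vec.min(), vec.max()
    if hi == lo:
        return np.zeros_like(vec)
    return (vec - lo) / (hi - lo)


def build_tensor(
    signal: PairSignal,
    max_samples: int = TENSOR_ROWS,
    total: int = TENSOR_LENGTH,
) -> FeatureTensor:
    """Assemble the (150, 6, 3) scaled tensor for one pair.

    Per sample: the three segments are resampled to their allocated
    position counts, concatenated to one 150-vector, min-max scaled to
    [0, 1] (an all-equal vector becomes all zeros), then split into three
    channels zeroed outside their region.  Fewer than six samples are tiled
    cyclically to fill the six rows; more than six, the first six are used.
    """
    n_samples = len(signal.gene1)
    if n_samples < 1:
        raise ValueError("signal must contain at least one sample")
    len1 = len(signal.gene1[0])
    lenI = len(signal.igr[0])
    len2 = len(signal.gene2[0])
    n1, nI, n2 = allocate_positions(len1, lenI, len2, total=total)
    rows = []
    for s in range(min(n_samples, max_samples)):
        parts = [resample_segment(signal.gene1[s], n1)]
        if nI > 0:
            parts.append(resample_segment(signal.igr[s], nI))
        parts.append(resample_segment(signal.gene2[s], n2))
        rows.append(_minmax_scale(np.concatenate(parts)))
    # tile cyclically up to the fixed row count
    full_rows = [rows[s % len(rows)] for s in range(TENSOR_ROWS)]
    values = np.zeros((total, TENSOR_ROWS, TENSOR_CHANNELS), dtype=np.float32)
    for r, vec in enumerate(full_rows):
        values[:n1, r, 0] = vec[:n1]
        values[n1:n1 + nI, r, 1] = vec[n1:n1 + nI]
        values[n1 + nI:, r, 2] = vec[n1 + nI:]
    return FeatureTensor(pair_id=signal.pair_id, values=values,
                         boundaries=(n1, nI, n2))


@dataclass
class PairDataset:
    """Labeled tensor dataset for a set of gene pairs."""

    tensors: np.ndarray  # (N, 150, 6, 3) float32
    labels: np.ndarray  # (N,) int8, values in {0, 1, 2}
    pair_ids: list[str]
    boundaries: np.ndarray  # (N, 3) int
    sample_ids: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.pair_ids)
        if self.tensors.shape != (n, TENSOR_LENGTH, TENSOR_ROWS, TENSOR_CHANNELS):
            raise ValueError(
                f"tensors shape {self.tensors.shape} inconsistent with "
                f"{n} pairs"
            )
        if self.labels.shape != (n,) or self.boundaries.shape != (n, 3):
            raise ValueError("labels/boundaries shapes inconsistent with pairs")

    def __len__(self) -> int:
        return len(self.pair_ids)

    def subset(self, index: np.ndarray) -> "PairDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return PairDataset(
            tensors=self.tensors[index],
            labels=self.labels[index],
            pair_ids=[self.pair_ids[i] for i in index],
            boundaries=self.boundaries[index],
            sample_ids=list(self.sample_ids),
            config=dict(self.config),
        )


def build_dataset(
    pairs: Sequence[GenePair],
    tracks: Sequence[CoverageTrack],
    labels: dict[str, int] | None = None,
    max_samples: int = TENSOR_ROWS,
    reorient_minus: bool = True,
) -> PairDataset:
    """Build tensors (and attach labels, default 2 = unknown) for pairs."""
    tensors = np.zeros(
        (len(pairs), TENSOR_LENGTH, TENSOR_ROWS, TENSOR_CHANNELS), dtype=np.float32
    )
    bounds = np.zeros((len(pairs), 3), dtype=np.int64)
    lab = np.full(len(pairs), 2, dtype=np.int8)
    for i, pair in enumerate(pairs):
        signal = extract_pair_signal(pair, tracks, reorient_minus=reorient_minus)
        ft = build_tensor(signal, max_samples=max_samples)
        tensors[i] = ft.values
        bounds[i] = ft.boundaries
        if labels is not None and pair.pair_id in labels:
            lab[i] = labels[pair.pair_id]
    return PairDataset(
        tensors=tensors,
        labels=lab,
        pair_ids=[p.pair_id for p in pairs],
        boundaries=bounds,
        sample_ids=[t.sample_id for t in tracks],
        config={"max_samples": max_samples, "reorient_minus": reorient_minus},
    )


def write_dataset(dataset: PairDataset, path: str | Path) -> None:
    """Write a dataset as a directory: ``data.npz`` + ``manifest.json``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(
        path / "data.npz",
        tensors=dataset.tensors.astype(np.float32),
        labels=dataset.labels.astype(np.int8),
        boundaries=dataset.boundaries.astype(np.int64),
        pair_ids=np.array(dataset.pair_ids, dtype=object),
    )
    manifest = {
        "format_version": DATASET_FORMAT_VERSION,
        "n_pairs": len(dataset),
        "tensor_shape": [TENSOR_LENGTH, TENSOR_ROWS, TENSOR_CHANNELS],
        "sample_ids": dataset.sample_ids,
        "config": dataset.config,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_dataset(path: str | Path) -> PairDataset:
    """Read a dataset archive, verifying shapes against the manifest."""
    path = Path(path)
    try:
        manifest = json.loads((path / "manifest.json").read_text())
        with np.load(path / "data.npz", allow_pickle=True) as npz:
            tensors = npz["tensors"]
            labels = npz["labels"]
            boundaries = npz["boundaries"]
            pair_ids = [str(p) for p in npz["pair_ids"]]
    except DatasetIntegrityError:
        raise
    except Exception as exc:
        raise DatasetIntegrityError(f"cannot read dataset at {path}: {exc}") from exc
    if manifest.get("n_pairs") != len(pair_ids) or tensors.shape[0] != len(pair_ids):
        raise DatasetIntegrityError(
            f"manifest n_pairs={manifest.get('n_pairs')} does not match "
            f"archive ({len(pair_ids)} ids, {tensors.shape[0]} tensors)"
        )
    if list(tensors.shape[1:]) != manifest.get("tensor_shape"):
        raise DatasetIntegrityError("tensor shape does not match manifest")
    return PairDataset(
        tensors=tensors,
        labels=labels,
        pair_ids=pair_ids,
        boundaries=boundaries,
        sample_ids=list(manifest.get("sample_ids", [])),
        config=dict(manifest.get("config", {})),
    )
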