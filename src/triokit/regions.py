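"""Region planning and training-example shuffling.

Training a variant-calling model streams labeled examples in a random
order, but producing and shuffling them genome-wide in one job is
infeasible on a scheduler-managed cluster. The approach here batches the
callable genome into N region files, each drawing windows from across the
genome so every region is a representative sample of the whole; examples
are then shuffled within each region independently (embarrassingly
parallel), shards concatenated, and finally interleaved across regions
into one randomized stream.

The number of regions is driven by the truth callset: N = ceil(total
truth variants / examples-per-region target). Windows are assigned to
regions by a seeded round-robin over the window list sorted by descending
variant count: within each consecutive block of N windows, a fresh random
permutation of the regions receives one window apiece. Because the blocks
are count-sorted, the spread between any two regions' totals never
exceeds the largest single window's count, and the random permutations
scatter each contig's windows over all regions.

Shards are JSON-lines files, one example per line with the payload
base64-encoded — a neutral stand-in for the binary tensor format the
training stack consumes, keeping the dataflow testable.
"""

from __future__ import annotations

import base64
import json
import math
import random
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .core_io import GenomeIndex, IntervalSet, VariantRecord

__all__ = [
    "ExampleRecord",
    "RegionPlan",
    "plan_regions",
    "shuffle_shard",
    "concat_shards",
    "split_shard",
    "interleave_global",
    "read_shard",
    "write_shard",
]

_SCHEMA_KEYS = frozenset({"contig", "pos", "ref", "alt", "label", "payload"})


@dataclass(frozen=True)
class ExampleRecord:
    """One labeled training example: a candidate variant plus its payload.

    ``payload`` stands in for the pileup tensor and is treated as opaque
    bytes everywhere.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    label: str
    payload: bytes = b""

    def to_json_line(self) -> str:
        return json.dumps(
            {
                "contig": self.contig,
                "pos": self.pos,
                "ref": self.ref,
                "alt": self.alt,
                "label": self.label,
                "payload": base64.b64encode(self.payload).decode("ascii"),
            },
            sort_keys=True,
        )

    @classmethod
    def from_json_line(cls, line: str) -> "ExampleRecord":
        obj = json.loads(line)
        if set(obj) != _SCHEMA_KEYS:
            raise ValueError(f"shard schema mismatch: fields {sorted(obj)}")
        return cls(
            contig=obj["contig"],
            pos=int(obj["pos"]),
            ref=obj["ref"],
            alt=obj["alt"],
            label=obj["label"],
            payload=base64.b64decode(obj["payload"]),
        )

    def sort_key(self) -> tuple:
        return (self.contig, self.pos, self.ref, self.alt)


def write_shard(examples: Iterable[ExampleRecord], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for ex in examples:
            fh.write(ex.to_json_line() + "\n")
            n += 1
    return n


def read_shard(path: str | Path) -> list[ExampleRecord]:
    with open(path) as fh:
        return [ExampleRecord.from_json_line(line) for line in fh if line.strip()]


@dataclass
class RegionPlan:
    """A partition of the windowed callable genome into balanced regions."""

    n_regions: int
    regions: list[IntervalSet]
    seed: int
    window_size: int
    examples_per_region_target: int
    variant_counts: list[int]

    def write_beds(self, out_dir: str | Path, prefix: str = "region") -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        width = max(3, len(str(self.n_regions)))
        for i, region in enumerate(self.regions, 1):
            path = out_dir / f"{prefix}_{i:0{width}d}.bed"
            with open(path, "w") as fh:
                for contig, start, end in region:
                    fh.write(f"{contig}\t{start}\t{end}\n")
            paths.append(path)
        return paths


def _tile_windows(
    callable_regions: IntervalSet, window_size: int
) -> list[tuple[str, int, int]]:
    windows = []
    for contig, start, end in callable_regions:
        for wstart in range(start, end, window_size):
            windows.append((contig, wstart, min(wstart + window_size, end)))
    return windows


def plan_regions(
    truth: Iterable[VariantRecord],
    callable_regions: IntervalSet,
    genome: GenomeIndex,
    examples_per_region: int,
    window_size: int = 10_000,
    seed: int = 0,
) -> RegionPlan:
    """Partition the callable genome into variant-count-balanced regions.

    The truth stream (already restricted to callable regions) sets
    N = ceil(variants / examples_per_region). The callable genome is tiled
    into windows of ``window_size`` bp and windows are dealt to regions by
    seeded round-robin over the descending-count order, so per-region
    counts are balanced to within one window's count and every region
    draws windows from across the genome.
    """
    if examples_per_region <= 0:
        raise ValueError("examples_per_region must be positive")
    windows = _tile_windows(callable_regions, window_size)

    by_contig_starts: dict[str, list[int]] = {}
    window_index: dict[str, list[int]] = {}
    for idx, (contig, wstart, _wend) in enumerate(windows):
        by_contig_starts.setdefault(contig, []).append(wstart)
        window_index.setdefault(contig, []).append(idx)

    counts = [0] * len(windows)
    total = 0
    for rec in truth:
        starts = by_contig_starts.get(rec.contig)
        if not starts:
            continue
        pos0 = rec.pos - 1
        i = bisect_right(starts, pos0) - 1
        if i < 0:
            continue
        idx = window_index[rec.contig][i]
        if pos0 < windows[idx][2]:
            counts[idx] += 1
            total += 1
    if total == 0:
        raise ValueError("empty truth set: no truth variants in callable regions")

    n_regions = math.ceil(total / examples_per_region)
    rank = {name: i for i, name in enumerate(genome.names)}
    order = sorted(
        range(len(windows)),
        key=lambda i: (
            -counts[i],
            rank.get(windows[i][0], len(rank)),
            windows[i][1],
        ),
    )

    rng = random.Random(seed)
    assignment: list[list[tuple[str, int, int]]] = [[] for _ in range(n_regions)]
    region_counts = [0] * n_regions
    for block_start in range(0, len(order), n_regions):
        block = order[block_start : block_start + n_regions]
        perm = list(range(n_regions))
        rng.shuffle(perm)
        for widx, region in zip(block, perm):
            assignment[region].append(windows[widx])
            region_counts[region] += counts[widx]

    return RegionPlan(
        n_regions=n_regions,
        regions=[IntervalSet(ivs, genome=genome) for ivs in assignment],
        seed=seed,
        window_size=window_size,
        examples_per_region_target=examples_per_region,
        variant_counts=region_counts,
    )


def shuffle_shard(
    examples: Sequence[ExampleRecord], seed: int
) -> list[ExampleRecord]:
    """Return a seeded Fisher–Yates permutation of the examples.

    The output is a permutation of the input (multiset equality); the same
    seed always reproduces the same order.
    """
    out = list(examples)
    random.Random(seed).shuffle(out)
    return out


def concat_shards(
    shard_paths: Sequence[str | Path], out_path: str | Path
) -> list[int]:
    """Concatenate shard files in the given order into one shard file.

    Returns the per-input record counts (the split boundaries), so the
    concatenation can be re-split into the original shards exactly.
    Shards must share the example schema.
    """
    boundaries = []
    with open(out_path, "w") as out:
        for path in shard_paths:
            n = 0
            with open(path) as fh:
                for line in fh:
                    if not line.strip():
                        continue
                    ExampleRecord.from_json_line(line)  # schema check
                    out.write(line if line.endswith("\n") else line + "\n")
                    n += 1
            boundaries.append(n)
    return boundaries


def split_shard(
    path: str | Path, boundaries: Sequence[int], out_paths: Sequence[str | Path]
) -> None:
    """Inverse of :func:`concat_shards` at recorded boundaries."""
    if len(boundaries) != len(out_paths):
        raise ValueError("boundaries and out_paths must have equal length")
    with open(path) as fh:
        lines = [line for line in fh if line.strip()]
    if sum(boundaries) != len(lines):
        raise ValueError("boundaries do not sum to the shard's record count")
    offset = 0
    for n, out_path in zip(boundaries, out_paths):
        with open(out_path, "w") as out:
            out.writelines(lines[offset : offset + n])
        offset += n


def interleave_global(
    region_shards: Sequence[Sequence[ExampleRecord] | str | Path], seed: int
) -> Iterator[ExampleRecord]:
    """Randomly interleave already-shuffled region shards into one stream.

    At each step a source shard is drawn with probability proportional to
    its remaining record count, preserving within-shard order, so the
    merged stream is a uniform random interleave. Deterministic given the
    seed; the record multiset is preserved.
    """
    queues: list[list[ExampleRecord]] = []
    for shard in region_shards:
        if isinstance(shard, (str, Path)):
            queues.append(read_shard(shard))
        else:
            queues.append(list(shard))
    positions = [0] * len(queues)
    remaining = [len(q) for q in queues]
    total = sum(remaining)
    rng = random.Random(seed)
    for _ in range(total):
        # weighted draw over shards by remaining count
        r = rng.randrange(sum(remaining))
        acc = 0
        for i, n in enumerate(remaining):
            acc += n
            if r < acc:
                break
        yield queues[i][positions[i]]
        positions[i] += 1
        remaining[i] -= 1
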