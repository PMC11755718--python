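"""Aggregation of per-frame interaction records into persistence fractions,
type-over-time heatmaps, per-residue accumulated counts, key-residue calls
and native-interaction percentage series.

Persistence of a (residue pair, type) row is the fraction of frames in
which at least one such contact exists; summed over types a pair may exceed
1 (simultaneous contacts of different types).  The native-interaction series
scores each frame against the residue pairs detected in a reference complex
— pairwise for native complexes, one-sided for cross-docked ones where only
the reference-side residues are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import defaultdict

import numpy as np
import pandas as pd

from .structures import Frame, ResidueKey
from .interactions import (InteractionCriteria, InteractionRecord,
                           detect_interactions, ITYPES)


class DegenerateReferenceError(Exception):
    pass


@dataclass
class PersistenceTable:
    """Per (pair, type) frame fractions plus pair-level summed fraction."""

    per_type: pd.DataFrame   # columns: pairA, pairB, type, fraction
    n_frames: int

    @property
    def pair_sum(self) -> pd.DataFrame:
        """Summed fraction per pair over types; may exceed 1."""
        if self.per_type.empty:
            return pd.DataFrame(columns=["pairA", "pairB", "summed_fraction"])
        g = (self.per_type.groupby(["pairA", "pairB"], sort=True)["fraction"]
             .sum().reset_index())
        return g.rename(columns={"fraction": "summed_fraction"})

    def rows(self):
        return list(self.per_type.itertuples(index=False))

    def to_csv(self, path) -> None:
        self.per_type.to_csv(path, index=False)


def persistence(records: list[InteractionRecord], n_frames: int) -> PersistenceTable:
    """fraction(pair, type) = #frames with ≥1 such record / n_frames."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    frames_seen: dict[tuple, set] = defaultdict(set)
    pairs: dict[tuple, tuple] = {}
    for r in records:
        if r.frame_index >= n_frames:
            raise ValueError(f"record frame {r.frame_index} >= n_frames {n_frames}")
        k = (str(r.pair[0]), str(r.pair[1]), r.itype)
        frames_seen[k].add(r.frame_index)
        pairs[k] = r.pair
    rows = [
        {"pairA": a, "pairB": b, "type": t, "fraction": len(fr) / n_frames}
        for (a, b, t), fr in sorted(frames_seen.items())
    ]
    df = pd.DataFrame(rows, columns=["pairA", "pairB", "type", "fraction"])
    return PersistenceTable(per_type=df, n_frames=n_frames)


def report_filter(table: PersistenceTable, min_fraction: float = 0.10) -> PersistenceTable:
    """Keep rows strictly above ``min_fraction`` (the >10 %-of-frames rule)."""
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be in [0, 1]")
    kept = table.per_type[table.per_type["fraction"] > min_fraction].reset_index(drop=True)
    return PersistenceTable(per_type=kept, n_frames=table.n_frames)


@dataclass
class TypeTimeHeatmap:
    """Counts of active records per (time bin, interaction type)."""

    counts: pd.DataFrame        # index: bin start (ns); columns: ITYPES
    bin_width_ns: float

    def to_csv(self, path) -> None:
        self.counts.to_csv(path, index_label="bin_start_ns")


def type_heatmap(records: list[InteractionRecord], times_ns,
                 bin_width_ns: float = 3.0,
                 total_time_ns: float | None = None) -> TypeTimeHeatmap:
    """Histogram of records over (time bin × type); Σ counts = Σ records."""
    if bin_width_ns <= 0:
        raise ValueError("bin_width_ns must be positive")
    times_ns = np.asarray(times_ns, dtype=float)
    if total_time_ns is None:
        total_time_ns = float(times_ns[-1]) if len(times_ns) else 0.0
    n_bins = max(1, int(np.ceil((total_time_ns + 1e-9) / bin_width_ns)))
    edges = np.arange(n_bins + 1) * bin_width_ns
    counts = np.zeros((n_bins, len(ITYPES)), dtype=int)
    col = {t: i for i, t in enumerate(ITYPES)}
    for r in records:
        t = times_ns[r.frame_index]
        b = min(int(t // bin_width_ns), n_bins - 1)
        counts[b, col[r.itype]] += 1
    df = pd.DataFrame(counts, index=edges[:-1], columns=list(ITYPES))
    return TypeTimeHeatmap(counts=df, bin_width_ns=bin_width_ns)


def residue_counts(tables: list[PersistenceTable],
                   min_fraction: float = 0.10,
                   prefilter: bool = True) -> pd.DataFrame:
    """Accumulated interaction count per residue across replicate runs.

    Each retained (pair, type) row of each replicate increments both partner
    residues by one; counts are summed over replicates.  The >10 % display
    filter is applied first by default, mirroring how reported interactions
    feed the accumulated-count figure.
    """
    if not tables:
        raise ValueError("at least one replicate table required")
    counts: dict[str, int] = defaultdict(int)
    for table in tables:
        t = report_filter(table, min_fraction) if prefilter else table
        for row in t.per_type.itertuples(index=False):
            counts[row.pairA] += 1
            counts[row.pairB] += 1
    df = pd.DataFrame(
        [{"residue": res, "count": c} for res, c in sorted(counts.items())],
        columns=["residue", "count"],
    )
    return df


def key_residues(counts: pd.DataFrame, threshold: int = 5) -> set[str]:
    """Residues with strictly more than ``threshold`` accumulated interactions."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if counts.empty:
        return set()
    return set(counts.loc[counts["count"] > threshold, "residue"])


@dataclass
class NativeReferenceSet:
    """Residue pairs defining the native interface of a reference complex."""

    pairs: set[tuple[ResidueKey, ResidueKey]]
    mode: str = "pairwise"              # or "one_sided_groupA"
    types: dict | None = None           # optional per-pair type annotations

    def __post_init__(self):
        if not self.pairs:
            raise DegenerateReferenceError("native reference set is empty")
        if self.mode not in ("pairwise", "one_sided_groupA"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def groupA_residues(self) -> set[ResidueKey]:
        return {a for a, _ in self.pairs}


def native_reference_from_complex(reference: Frame, groupA, groupB,
                                  criteria: InteractionCriteria | None = None,
                                  mode: str = "pairwise") -> NativeReferenceSet:
    """Inter-group residue pairs with ≥1 detected contact of any type."""
    records = detect_interactions(reference, groupA, groupB, criteria)
    pairs = {r.pair for r in records}
    if not pairs:
        raise DegenerateReferenceError(
            "no inter-group interactions detected in the reference complex")
    types: dict = defaultdict(set)
    for r in records:
        types[r.pair].add(r.itype)
    return NativeReferenceSet(pairs=pairs, mode=mode, types=dict(types))


@dataclass
class NativeFractionSeries:
    time_ns: np.ndarray
    percent: np.ndarray

    def __post_init__(self):
        self.time_ns = np.asarray(self.time_ns, dtype=float)
        self.percent = np.asarray(self.percent, dtype=float)
        if self.time_ns.shape != self.percent.shape:
            raise ValueError("length mismatch")
        if np.any((self.percent < 0) | (self.percent > 100)):
            raise ValueError("percent values must lie in [0, 100]")

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_ns": self.time_ns,
                      "native_pct": self.percent}).to_csv(path, index=False)


def native_fraction_series(records: list[InteractionRecord],
                           reference: NativeReferenceSet,
                           times_ns, n_frames: int | None = None,
                           typed: bool = False) -> NativeFractionSeries:
    """Per-frame percentage of native interactions that are present.

    pairwise mode: 100 · |native pairs with ≥1 record| / |native set|.
    one_sided_groupA mode: a native groupA residue counts as recovered when
    it contacts ANY partner in the frame; normalised over distinct native
    groupA residues.  ``typed`` additionally requires a record of one of the
    reference pair's annotated types (pairwise mode only).
    """
    times_ns = np.asarray(times_ns, dtype=float)
    if n_frames is None:
        n_frames = len(times_ns)
    if typed and reference.types is None:
        raise ValueError("typed matching requires per-pair type annotations")

    by_frame: dict[int, list[InteractionRecord]] = defaultdict(list)
    for r in records:
        by_frame[r.frame_index].append(r)

    pct = np.zeros(n_frames)
    if reference.mode == "pairwise":
        denom = len(reference.pairs)
        for f in range(n_frames):
            present = 0
            frame_pairs: dict = defaultdict(set)
            for r in by_frame.get(f, ()):
                frame_pairs[r.pair].add(r.itype)
            for pair in reference.pairs:
                got = frame_pairs.get(pair)
                if not got:
                    continue
                if typed and not (got & reference.types[pair]):
                    continue
                present += 1
            pct[f] = 100.0 * present / denom
    else:  # one_sided_groupA
        native_a = reference.groupA_residues
        denom = len(native_a)
        for f in range(n_frames):
            touched = {r.pair[0] for r in by_frame.get(f, ())}
            pct[f] = 100.0 * len(native_a & touched) / denom
    return NativeFractionSeries(time_ns=times_ns[:n_frames], percent=pct)


def summary_json(key_set: set[str], counts: pd.DataFrame, path) -> None:
    import json
    payload = {
        "key_residues": sorted(key_set),
        "residue_counts": {r.residue: int(r.count)
                           for r in counts.itertuples(index=False)},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
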