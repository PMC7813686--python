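"""Beat segmentation, label mapping, class balancing and ten-fold planning.

Conventions (all configurable where noted):

* indices are 0-based, windows half-open;
* a beat window of width ``w`` spans ``[r - w/2, r + w/2)`` so the R peak
  sits at 0-based offset ``w/2`` (180 for the default 360-sample window);
* beats whose window would cross a record boundary are dropped and counted;
* every segment is z-scored (population SD) after slicing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .preprocess import DegenerateSegmentError, zscore
from .synthetic import ECGRecord  # noqa: F401  (canonical record container)

logger = logging.getLogger("ecgbeats")

#: Beat classes in study order; MIT-BIH code -> class name.
CLASS_NAMES = ("NOR", "LBBB", "RBBB", "AP", "PVC")
_SYMBOL_MAP = {"N": 0, "L": 1, "R": 2, "A": 3, "V": 4}
EXCLUDED = "excluded"

SEGMENT_WIDTH = 360  # samples (= 1 s at 360 Hz)
R_OFFSET = SEGMENT_WIDTH // 2  # R peak at 0-based offset 180


class EmptyClassError(ValueError):
    """A class with a positive balancing target has no source segments."""


def map_symbol(symbol: str) -> int | str:
    """MIT-BIH annotation code -> class index 0..4, or ``"excluded"``.

    N -> NOR, L -> LBBB, R -> RBBB, A -> AP, V -> PVC; every other code
    (paced, fusion, aberrated, ...) is excluded from the five-class study.
    """
    return _SYMBOL_MAP.get(symbol, EXCLUDED)


@dataclass
class BeatSegment:
    """One R-centred, z-scored beat window."""

    values: np.ndarray  # length SEGMENT_WIDTH, mean ~0, population SD ~1
    label: int  # class index 0..4
    source_record: str
    r_index: int

    @property
    def class_name(self) -> str:
        return CLASS_NAMES[self.label]


@dataclass
class SegmentationReport:
    segments: list[BeatSegment]
    n_boundary_dropped: int = 0
    n_excluded_symbols: int = 0
    n_degenerate: int = 0


def segment_beats(
    record: ECGRecord,
    r_indices: np.ndarray | None = None,
    symbols: list[str] | None = None,
    width: int = SEGMENT_WIDTH,
) -> SegmentationReport:
    """Slice z-scored beat windows centred on R peaks.

    By default the record's own annotations supply both the R locations and
    the beat symbols (the expert-annotation route); pass ``r_indices`` to
    use detector output instead, with ``symbols`` giving per-beat labels
    (defaults to the record's annotation symbols, matched by order).
    """
    if width % 2:
        raise ValueError("width must be even")
    if r_indices is None:
        r_indices = record.r_indices
        symbols = record.symbols
    elif symbols is None:
        symbols = record.symbols
    r_indices = np.asarray(r_indices, dtype=int)
    if len(symbols) != len(r_indices):
        raise ValueError("one symbol per R index required")

    half = width // 2
    n = len(record.samples)
    segments: list[BeatSegment] = []
    dropped = excluded = degenerate = 0
    for r, sym in zip(r_indices, symbols):
        label = map_symbol(sym)
        if label == EXCLUDED:
            excluded += 1
            continue
        lo, hi = r - half, r + half
        if lo < 0 or hi > n:
            dropped += 1
            continue
        raw = record.samples[lo:hi]
        try:
            values = zscore(raw)
        except DegenerateSegmentError:
            degenerate += 1
            continue
        segments.append(
            BeatSegment(values=values, label=int(label), source_record=record.record_id, r_index=int(r))
        )
    if dropped or excluded or degenerate:
        logger.warning(
            "segment_beats(%s): dropped=%d at boundaries, excluded=%d symbols, degenerate=%d",
            record.record_id, dropped, excluded, degenerate,
        )
    return SegmentationReport(segments, dropped, excluded, degenerate)


@dataclass(frozen=True)
class BalanceTargets:
    """Per-class target counts, in CLASS_NAMES order."""

    counts: tuple[int, int, int, int, int]

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.counts):
            raise ValueError("all balance targets must be > 0")


def balance(
    segments: list[BeatSegment], targets: BalanceTargets, seed: int = 0
) -> list[BeatSegment]:
    """Resample to exact per-class targets.

    Under-represented classes are padded by uniform duplication with
    replacement (originals all kept); over-represented classes are reduced
    by uniform subsampling without replacement; classes already at target
    pass through unchanged.  Output preserves class-block order.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[BeatSegment]] = {c: [] for c in range(5)}
    for s in segments:
        by_class[s.label].append(s)
    out: list[BeatSegment] = []
    for c in range(5):
        pool = by_class[c]
        target = targets.counts[c]
        if not pool:
            raise EmptyClassError(f"class {CLASS_NAMES[c]} has no segments")
        if len(pool) == target:
            out.extend(pool)
        elif len(pool) > target:
            keep = rng.choice(len(pool), size=target, replace=False)
            out.extend(pool[i] for i in sorted(keep))
        else:
            extra = rng.choice(len(pool), size=target - len(pool), replace=True)
            out.extend(pool)
            out.extend(pool[i] for i in extra)
    return out


@dataclass
class FoldPlan:
    """Stratified k-fold assignment: segment index -> fold id."""

    k: int
    assignment: np.ndarray
    seed: int

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def train_test(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = self.fold_indices(fold)
        train = np.flatnonzero(self.assignment != fold)
        return train, test


def make_folds(segments: list[BeatSegment], k: int = 10, seed: int = 0) -> FoldPlan:
    """Stratified k-fold plan (per-class fold counts differ by at most 1)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(segments) < k:
        raise ValueError("need at least k segments")
    labels = np.array([s.label for s in segments])
    present = np.unique(labels)
    counts = np.bincount(labels, minlength=5)
    assignment = np.empty(len(segments), dtype=int)
    if np.all(counts[present] >= k):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
        for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(segments)), labels)):
            assignment[test_idx] = fold
    else:
        # some class has < k members: spread as evenly as possible using the
        # same interleaved allocation StratifiedKFold uses, without its check
        logger.warning(
            "some classes have fewer than k=%d members; spreading as evenly as possible", k
        )
        rng = np.random.default_rng(seed)
        y_order = np.sort(labels)
        alloc = np.stack(
            [np.bincount(y_order[i::k], minlength=5) for i in range(k)]
        )  # alloc[fold, class] = how many of that class the fold receives
        for c in present:
            members = rng.permutation(np.flatnonzero(labels == c))
            pos = 0
            for fold in range(k):
                take = alloc[fold, c]
                assignment[members[pos : pos + take]] = fold
                pos += take
    return FoldPlan(k=k, assignment=assignment, seed=seed)


def segments_to_arrays(segments: list[BeatSegment]) -> tuple[np.ndarray, np.ndarray]:
    """Stack segments into (n, width) float32 X and (n,) int y arrays."""
    X = np.stack([s.values for s in segments]).astype(np.float32)
    y = np.array([s.label for s in segments], dtype=int)
    return X, y
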