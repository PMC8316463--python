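"""Duration-normalized gaze scanpaths: encoding, alignment similarity, and
characteristic (barycenter) sequences.

A trial's gaze stream is collapsed to 100 equal time bins labeled ``T``
(target), ``P`` (path), or ``S`` (either avoidance margin); bins with no
in-AOI gaze become gap symbols (``-``).  The numeric view maps
T -> 2, P -> 5, S -> 10 (gaps absent).

Pairwise similarity is a global Needleman-Wunsch alignment score normalized
into [0, 1] by the best attainable self-match.  The alignment engine is
Bio.Align's ``PairwiseAligner`` (global mode); tests hold it to an
independent brute-force recursion.

Characteristic sequences are computed with DTW barycenter averaging (DBA):
iterative reassignment of frames along DTW paths and per-coordinate
averaging, which never increases the summed squared DTW distance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .gaze import AoiRegions, label_points, sample_dwells

try:  # numba accelerates the DTW inner loops; plain numpy otherwise
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

logger = logging.getLogger(__name__)

__all__ = [
    "SYMBOLS",
    "GAP",
    "NUMERIC",
    "ScanpathSequence",
    "SequenceSetMatrices",
    "ScoringScheme",
    "encode_sequence",
    "build_matrices",
    "similarity",
    "similarity_matrix",
    "characteristic_sequence",
    "export_fasta",
    "read_fasta",
    "dtw_distance",
]

SEQUENCE_LENGTH = 100
SYMBOLS = ("T", "P", "S")
GAP = "-"
NUMERIC = {"T": 2.0, "P": 5.0, "S": 10.0}
_GAP_LETTER = "X"  # internal stand-in: Bio.Align reserves '-' for alignment gaps


@dataclass(frozen=True)
class ScanpathSequence:
    """100-symbol duration-normalized AOI string with its numeric view."""

    symbols: tuple[str, ...]
    trial_id: str | None = None
    condition_id: int | None = None

    def __post_init__(self) -> None:
        if len(self.symbols) != SEQUENCE_LENGTH:
            raise ValueError(f"scanpath must have {SEQUENCE_LENGTH} symbols")
        bad = set(self.symbols) - set(SYMBOLS) - {GAP}
        if bad:
            raise ValueError(f"invalid symbols {bad}")

    @property
    def numeric(self) -> np.ndarray:
        """T -> 2, P -> 5, S -> 10; NaN for gap bins."""
        return np.array([NUMERIC.get(s, np.nan) for s in self.symbols])

    @property
    def string(self) -> str:
        return "".join(self.symbols)

    def numeric_filled(self) -> np.ndarray:
        """Numeric view with gaps filled by carrying the last label (leading
        gaps take the first label; an all-gap sequence raises)."""
        vals = self.numeric
        if np.isnan(vals).all():
            raise ValueError("all-gap scanpath cannot be gap-filled")
        idx = np.arange(len(vals))
        good = ~np.isnan(vals)
        prev = np.maximum.accumulate(np.where(good, idx, -1))
        first = idx[good][0]
        prev = np.where(prev < 0, first, prev)
        return vals[prev]


@dataclass(frozen=True)
class SequenceSetMatrices:
    """Matrix A (symbols), Matrix B (numeric), Matrix C (per-bin means)."""

    matrix_a: np.ndarray  # (N, 100) of single-char strings
    matrix_b: np.ndarray  # (N, 100) floats, NaN for gaps
    matrix_c: np.ndarray  # (100,) per-column mean over non-gap entries


def encode_sequence(
    trial, regions: AoiRegions, gap_mode: str = "gap"
) -> ScanpathSequence:
    """Encode one trial into a 100-bin scanpath.

    Each bin takes the majority in-AOI token among its gaze samples
    (margins merged into ``S``); ties break by longer dwell, then the fixed
    order T > S > P.  Bins without in-AOI samples become gaps
    (``gap_mode="gap"``) or repeat the previous label
    (``gap_mode="carry"``).
    """
    gaze = trial.gaze
    if len(gaze) == 0:
        raise ValueError("trial has no gaze samples")
    t = gaze["t_s"].to_numpy(dtype=float)
    labels = label_points(gaze["x_cm"].to_numpy(), gaze["y_cm"].to_numpy(), regions)
    merged = np.where(np.char.startswith(labels.astype(str), "S_"), "S", labels)
    dwell = sample_dwells(t)
    t0, t1 = float(t[0]), float(t[-1])
    span = max(t1 - t0, 1e-9)
    bins = np.minimum(
        ((t - t0) / span * SEQUENCE_LENGTH).astype(int), SEQUENCE_LENGTH - 1
    )
    symbols: list[str] = []
    for b in range(SEQUENCE_LENGTH):
        mask = bins == b
        toks = merged[mask]
        in_aoi = np.isin(toks, SYMBOLS)
        if not in_aoi.any():
            symbols.append(GAP)
            continue
        toks = toks[in_aoi]
        dw = dwell[mask][in_aoi]
        counts = {s: int((toks == s).sum()) for s in SYMBOLS if (toks == s).any()}
        top = max(counts.values())
        tied = [s for s, c in counts.items() if c == top]
        if len(tied) > 1:
            dwells = {s: float(dw[toks == s].sum()) for s in tied}
            top_dw = max(dwells.values())
            tied = [s for s in tied if dwells[s] >= top_dw - 1e-12]
            tied.sort(key=lambda s: ("T", "S", "P").index(s))
        symbols.append(tied[0])
    if gap_mode == "carry":
        filled = []
        last = None
        for s in symbols:
            if s == GAP and last is not None:
                s = last
            elif s != GAP:
                last = s
            filled.append(s)
        # leading gaps take the first real label, if any
        if last is not None:
            first_real = next(s for s in filled if s != GAP)
            filled = [first_real if s == GAP else s for s in filled]
        symbols = filled
    elif gap_mode != "gap":
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    return ScanpathSequence(
        tuple(symbols),
        trial_id=getattr(trial, "trial_id", None),
        condition_id=getattr(trial, "condition_id", None),
    )


def build_matrices(sequences: Sequence[ScanpathSequence]) -> SequenceSetMatrices:
    """Stack sequences into Matrices A/B and the per-bin mean Matrix C.

    Matrix C averages the numeric codes over non-gap rows per column; a
    column that is gap in every row is NaN there.
    """
    if not sequences:
        raise ValueError("no sequences")
    a = np.array([list(s.symbols) for s in sequences])
    b = np.array([s.numeric for s in sequences])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        c = np.nanmean(b, axis=0)
    return SequenceSetMatrices(matrix_a=a, matrix_b=b, matrix_c=c)


@dataclass(frozen=True)
class ScoringScheme:
    """Needleman-Wunsch scoring: identity by default, optionally graded by
    numeric distance (T-P counts as closer than T-S).

    Gap bins (symbols with no in-AOI gaze) score 0 against everything,
    including themselves, so they earn no match credit.
    """

    match: float = 1.0
    mismatch: float = 0.0
    gap: float = 0.0  # insertion/deletion score (open == extend)
    graded: bool = False

    def substitution(self, a: str, b: str) -> float:
        if a == GAP or b == GAP:
            return 0.0
        if self.graded:
            span = max(NUMERIC.values()) - min(NUMERIC.values())
            return self.match - abs(NUMERIC[a] - NUMERIC[b]) / span * (
                self.match - self.mismatch
            )
        return self.match if a == b else self.mismatch

    def aligner(self) -> PairwiseAligner:
        alphabet = "".join(SYMBOLS) + _GAP_LETTER
        matrix = substitution_matrices.Array(alphabet, dims=2)
        for x in alphabet:
            for y in alphabet:
                sx = GAP if x == _GAP_LETTER else x
                sy = GAP if y == _GAP_LETTER else y
                matrix[x, y] = self.substitution(sx, sy)
        aligner = PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = matrix
        aligner.open_gap_score = self.gap
        aligner.extend_gap_score = self.gap
        return aligner


def _aligner_string(seq: ScanpathSequence | Sequence[str] | str) -> str:
    if isinstance(seq, ScanpathSequence):
        s = seq.string
    elif isinstance(seq, str):
        s = seq
    else:
        s = "".join(seq)
    return s.replace(GAP, _GAP_LETTER)


def alignment_score(a, b, scheme: ScoringScheme = ScoringScheme()) -> float:
    """Raw global-alignment (NW) score between two symbol sequences."""
    aligner = scheme.aligner()
    return float(aligner.score(_aligner_string(a), _aligner_string(b)))


def similarity(a, b, scheme: ScoringScheme = ScoringScheme()) -> float:
    """Normalized NW similarity in [0, 1].

    The raw score is divided by the larger of the two self-match scores, so
    identical sequences score exactly 1.  Raises ``ValueError`` when the
    best attainable score is not positive (e.g. all-gap input under the
    default scheme).
    """
    aligner = scheme.aligner()
    sa, sb = _aligner_string(a), _aligner_string(b)
    denom = max(aligner.score(sa, sa), aligner.score(sb, sb))
    if denom <= 0:
        raise ValueError("maximum attainable alignment score is not positive")
    return float(aligner.score(sa, sb)) / float(denom)


def similarity_matrix(
    groups: Mapping[int, Sequence[ScanpathSequence]],
    scheme: ScoringScheme = ScoringScheme(),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """All-pairs similarity summarized per condition pair.

    Returns (mean, sd, long scores) frames.  Diagonal cells summarize
    within-condition pairs excluding self-pairs; the table is symmetric.
    """
    conds = sorted(groups)
    for c in conds:
        if len(groups[c]) < 1:
            raise ValueError(f"condition {c} has no sequences")
    if sum(len(groups[c]) for c in conds) < 2:
        raise ValueError("need at least two sequences overall")
    aligner = scheme.aligner()
    strings = {c: [_aligner_string(s) for s in groups[c]] for c in conds}
    selfs = {
        c: [float(aligner.score(s, s)) for s in strings[c]] for c in conds
    }
    cells: dict[tuple[int, int], list[float]] = {}
    records = []
    for i, ci in enumerate(conds):
        for cj in conds[i:]:
            scores = []
            si, sj = strings[ci], strings[cj]
            for ai in range(len(si)):
                b_start = ai + 1 if ci == cj else 0
                for bj in range(b_start, len(sj)):
                    denom = max(selfs[ci][ai], selfs[cj][bj])
                    if denom <= 0:
                        raise ValueError("non-positive self-score in group")
                    val = float(aligner.score(si[ai], sj[bj])) / denom
                    scores.append(val)
                    records.append(
                        {"condition_a": ci, "condition_b": cj, "score": val}
                    )
            cells[(ci, cj)] = scores
    mean = pd.DataFrame(index=conds, columns=conds, dtype=float)
    sd = pd.DataFrame(index=conds, columns=conds, dtype=float)
    for (ci, cj), scores in cells.items():
        arr = np.asarray(scores)
        m = float(arr.mean()) if arr.size else np.nan
        s = float(arr.std(ddof=1)) if arr.size > 1 else np.nan
        mean.loc[ci, cj] = mean.loc[cj, ci] = m
        sd.loc[ci, cj] = sd.loc[cj, ci] = s
    return mean, sd, pd.DataFrame(records)


def export_fasta(sequences: Iterable[ScanpathSequence], path) -> None:
    """Write scanpaths as FASTA (residues T/P/S, '-' for gap bins)."""
    records = [
        SeqRecord(
            Seq(seq.string),
            id=seq.trial_id or f"scanpath_{i}",
            description="",
        )
        for i, seq in enumerate(sequences)
    ]
    if not records:
        logger.warning("export_fasta called with no sequences; writing empty file")
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> list[ScanpathSequence]:
    return [
        ScanpathSequence(tuple(str(rec.seq)), trial_id=rec.id)
        for rec in SeqIO.parse(path, "fasta")
    ]


# ---------------------------------------------------------------------------
# DTW / DBA

@njit(cache=True)
def _dtw_table(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    n, m = len(x), len(y)
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost = (x[i - 1] - y[j - 1]) ** 2
            best = acc[i - 1, j - 1]
            if acc[i - 1, j] < best:
                best = acc[i - 1, j]
            if acc[i, j - 1] < best:
                best = acc[i, j - 1]
            acc[i, j] = cost + best
    return acc


def dtw_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Dynamic-time-warping distance (sqrt of summed squared local costs)."""
    acc = _dtw_table(np.asarray(x, float), np.asarray(y, float))
    return float(np.sqrt(acc[-1, -1]))


def _dtw_path(x: np.ndarray, y: np.ndarray) -> tuple[float, list[tuple[int, int]]]:
    acc = _dtw_table(x, y)
    i, j = len(x), len(y)
    path = []
    while i > 0 and j > 0:
        path.append((i - 1, j - 1))
        steps = ((acc[i - 1, j - 1], i - 1, j - 1),
                 (acc[i - 1, j], i - 1, j),
                 (acc[i, j - 1], i, j - 1))
        _, i, j = min(steps, key=lambda s: s[0])
    path.reverse()
    return float(acc[-1, -1]), path


def characteristic_sequence(
    sequences: Sequence[ScanpathSequence] | Sequence[np.ndarray],
    max_iter: int = 30,
    tol: float = 1e-6,
) -> tuple[np.ndarray, list[float]]:
    """DTW barycenter average (numeric, length 100) of a sequence set.

    Scanpaths are gap-filled to numeric form first.  Initialization is the
    medoid (smallest summed DTW distance); each iteration reassigns frames
    along DTW paths and replaces every barycenter coordinate with the mean
    of its aligned values, stopping when the summed squared DTW distance
    stops improving.  Returns (barycenter, per-iteration objective values).
    """
    if len(sequences) == 0:
        raise ValueError("no sequences")
    series = [
        s.numeric_filled() if isinstance(s, ScanpathSequence) else np.asarray(s, float)
        for s in sequences
    ]
    n = len(series)
    if n == 1:
        only = series[0].copy()
        return only, [0.0]
    # medoid initialization
    dists = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dists[i, j] = dists[j, i] = _dtw_table(series[i], series[j])[-1, -1]
    center = series[int(np.argmin(dists.sum(axis=1)))].copy()
    objective: list[float] = []
    best = np.inf
    for _ in range(max_iter):
        sums = np.zeros_like(center)
        counts = np.zeros_like(center)
        total = 0.0
        for s in series:
            dist, path = _dtw_path(center, s)
            total += dist
            for ci, si in path:
                sums[ci] += s[si]
                counts[ci] += 1
        objective.append(total)
        if total > best + tol:  # guard: never report an increase
            break
        if best - total < tol:
            best = min(best, total)
            break
        best = total
        center = sums / np.maximum(counts, 1)
    return center, objective
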