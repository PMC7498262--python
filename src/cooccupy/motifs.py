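"""PWM scanning, the dinucleotide-shuffle null, and motif co-occurrence calls.

A window is scored on both strands at every offset by the log-odds sum
``sum_i log2(p_i(base) / bg(base))`` and rescaled to a *relative score*
``(score - min) / (max - min)`` where min/max are the scores of the worst
and best attainable words. Sites at relative score >= 0.70 are kept, each
peak's 150 bp summit window is labelled Sox-only / Tcf-only / both /
neither from the surviving sites, and label frequencies are compared to a
background built by dinucleotide-preserving shuffles of the same windows
(Altschul–Erickson Euler-path construction, 10 shuffles per window) with
one-sided Fisher tests.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .stats import ContingencyTable2x2, fisher_exact

__all__ = [
    "PWM",
    "MotifHit",
    "PeakMotifClass",
    "ShuffleSet",
    "EnrichmentResult",
    "read_motifs",
    "pwm_from_consensus",
    "scan_sequence",
    "dinucleotide_shuffle",
    "classify_peak",
    "classify_window",
    "motif_class_enrichment",
    "motif_spacing",
    "motif_count_summary",
    "SpacingResult",
    "MotifCountSummary",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_UNIFORM = np.full(4, 0.25)


@dataclass(frozen=True)
class PWM:
    """Position probability matrix with scanning machinery.

    ``probs`` is an L x 4 array in A, C, G, T order; rows sum to 1 and every
    entry is positive (a pseudocount is applied at construction).
    """

    name: str
    tf_class: str  # sox | tcf | other
    probs: np.ndarray
    source: str = "homer"
    pseudocount: float = 1e-3

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError(f"PWM {self.name}: probs must be L x 4")
        if probs.shape[0] < 4:
            raise ValueError(f"PWM {self.name}: length must be >= 4")
        if np.any(probs <= 0):
            raise ValueError(f"PWM {self.name}: entries must be positive after pseudocount")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.name}: rows must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in np.argmax(self.probs, axis=1))

    def log_odds(self, background: np.ndarray | None = None) -> np.ndarray:
        bg = _UNIFORM if background is None else np.asarray(background, dtype=float)
        return np.log2(self.probs / bg)


@dataclass(frozen=True)
class MotifHit:
    peak_id: str
    motif_name: str
    offset: int        # 0-based start within the scanned window
    strand: str        # + or -
    log_odds: float    # bits
    relative_score: float
    width: int         # motif length, for center arithmetic

    @property
    def center(self) -> float:
        return self.offset + self.width / 2


@dataclass(frozen=True)
class PeakMotifClass:
    peak_id: str
    label: str  # sox_and_tcf | sox_only | tcf_only | neither
    n_sox_sites: int
    n_tcf_sites: int

    def __post_init__(self) -> None:
        expected = _label_for(self.n_sox_sites, self.n_tcf_sites)
        if self.label != expected:
            raise ValueError(
                f"label {self.label!r} inconsistent with counts "
                f"({self.n_sox_sites}, {self.n_tcf_sites})"
            )


def _label_for(n_sox: int, n_tcf: int) -> str:
    if n_sox > 0 and n_tcf > 0:
        return "sox_and_tcf"
    if n_sox > 0:
        return "sox_only"
    if n_tcf > 0:
        return "tcf_only"
    return "neither"


@dataclass(frozen=True)
class ShuffleSet:
    original_id: str
    shuffles: tuple[str, ...]
    seed: int


@dataclass(frozen=True)
class EnrichmentResult:
    label: str
    a: int  # real with label
    b: int  # real without
    c: int  # background with
    d: int  # background without
    odds_ratio: float
    p_value: float


def _normalize_rows(rows: list[list[float]], name: str, pseudocount: float) -> np.ndarray:
    mat = np.asarray(rows, dtype=float)
    if np.any(mat < 0):
        raise ValueError(f"motif {name}: negative probability entries")
    sums = mat.sum(axis=1)
    bad = np.where(np.abs(sums - 1.0) > 0.01)[0]
    if bad.size:
        raise ValueError(
            f"motif {name}: row {bad[0] + 1} sums to {sums[bad[0]]:.4f}, not 1"
        )
    mat = mat + pseudocount
    return mat / mat.sum(axis=1, keepdims=True)


def read_motifs(
    path: str | os.PathLike,
    format: str = "homer",
    tf_class: str = "other",
    pseudocount: float = 1e-3,
) -> list[PWM]:
    """Read PWMs from HOMER ``.motif`` or CIS-BP text files.

    HOMER files hold one or more motifs, each a ``>consensus name score``
    header followed by one ``A C G T`` probability row per position. CIS-BP
    files hold a single matrix under a ``Pos A C G T`` header. Rows are
    renormalized after adding the pseudocount; a pre-normalization row sum
    off by more than 0.01 is an error.
    """
    path = os.fspath(path)
    pwms: list[PWM] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if format == "homer":
        name = None
        rows: list[list[float]] = []
        for ln in lines:
            if ln.startswith(">"):
                if name is not None:
                    if not rows:
                        raise ValueError(f"{path}: empty matrix for motif {name}")
                    pwms.append(PWM(name, tf_class, _normalize_rows(rows, name, pseudocount),
                                    "homer", pseudocount))
                parts = ln[1:].split()
                name = parts[1] if len(parts) > 1 else parts[0]
                rows = []
            elif ln.strip():
                vals = [float(x) for x in ln.split()]
                if len(vals) != 4:
                    raise ValueError(f"{path}: expected 4 columns, got {len(vals)}: {ln!r}")
                rows.append(vals)
        if name is None:
            raise ValueError(f"{path}: no motif header found")
        if not rows:
            raise ValueError(f"{path}: empty matrix for motif {name}")
        pwms.append(PWM(name, tf_class, _normalize_rows(rows, name, pseudocount),
                        "homer", pseudocount))
    elif format == "cisbp":
        body = [ln for ln in lines if ln.strip()]
        if not body or body[0].split()[:1] != ["Pos"]:
            raise ValueError(f"{path}: CIS-BP file must start with 'Pos A C G T' header")
        header = body[0].split()
        if header[1:5] != ["A", "C", "G", "T"]:
            raise ValueError(f"{path}: CIS-BP header columns must be A C G T")
        rows = []
        for ln in body[1:]:
            vals = ln.split()
            if len(vals) != 5:
                raise ValueError(f"{path}: expected 5 columns, got {len(vals)}: {ln!r}")
            rows.append([float(x) for x in vals[1:5]])
        if not rows:
            raise ValueError(f"{path}: empty CIS-BP matrix")
        name = os.path.splitext(os.path.basename(path))[0]
        pwms.append(PWM(name, tf_class, _normalize_rows(rows, name, pseudocount),
                        "cisbp", pseudocount))
    else:
        raise ValueError(f"unknown motif format {format!r}")
    return pwms


def pwm_from_consensus(
    consensus: str,
    name: str,
    tf_class: str,
    match_prob: float = 0.97,
) -> PWM:
    """Near-consensus PWM: ``match_prob`` at the consensus base, rest uniform."""
    if not consensus or any(b not in _BASE_INDEX for b in consensus.upper()):
        raise ValueError(f"consensus must be over ACGT, got {consensus!r}")
    off = (1.0 - match_prob) / 3.0
    probs = np.full((len(consensus), 4), off)
    for i, b in enumerate(consensus.upper()):
        probs[i, _BASE_INDEX[b]] = match_prob
    return PWM(name, tf_class, probs, source="consensus")


def encode_sequence(seq: str) -> np.ndarray:
    """ACGT -> 0..3 int8 array; any other letter (N etc.) -> -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _window_scores(idx: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Log-odds score of every window; windows containing N score -inf."""
    L = lo.shape[0]
    n_win = idx.size - L + 1
    if n_win <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    valid = np.all(windows >= 0, axis=1)
    scores = np.full(n_win, -np.inf)
    if valid.any():
        w = windows[valid]
        scores[valid] = lo[np.arange(L)[None, :], w].sum(axis=1)
    return scores


def scan_sequence(
    seq: str,
    pwm: PWM,
    rel_threshold: float = 0.70,
    background: Sequence[float] | None = None,
    peak_id: str = "",
) -> list[MotifHit]:
    """All hits of ``pwm`` in ``seq`` at relative score >= ``rel_threshold``.

    Both strands are scanned at every offset; offsets are reported in the
    forward coordinates of ``seq``. The relative score rescales the window
    log-odds between the per-position attainable minimum and maximum, so a
    perfect consensus word scores exactly 1. Windows containing N are
    excluded. Hits come back in ascending offset, + before - at equal offset.
    A sequence shorter than the motif yields an empty list.
    """
    if not (0 < rel_threshold <= 1):
        raise ValueError(f"rel_threshold must be in (0, 1], got {rel_threshold}")
    bg = _UNIFORM if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0) or np.any(bg <= 0):
        raise ValueError("background must be a positive 4-vector summing to 1")
    lo = pwm.log_odds(bg)
    lo_min = float(lo.min(axis=1).sum())
    lo_max = float(lo.max(axis=1).sum())
    span = lo_max - lo_min
    idx = encode_sequence(seq)
    L = len(pwm)
    if idx.size < L:
        return []
    fwd = _window_scores(idx, lo)
    # minus strand: score the reverse complement of each window, i.e. scan the
    # reverse-complemented sequence and map window j -> forward offset n-L-j
    rc_idx = (3 - idx[::-1]).astype(np.int8)
    rc_idx[idx[::-1] < 0] = -1
    rev = _window_scores(rc_idx, lo)[::-1]
    cut = lo_min + rel_threshold * span
    candidates: list[tuple[int, int, str, float]] = []
    for strand_rank, strand, scores in ((0, "+", fwd), (1, "-", rev)):
        for off in np.flatnonzero(np.isfinite(scores) & (scores >= cut - 1e-12)):
            candidates.append((int(off), strand_rank, strand, float(scores[off])))
    candidates.sort(key=lambda t: (t[0], t[1]))
    hits: list[MotifHit] = []
    for off, _, strand, score in candidates:
        rel = (score - lo_min) / span if span > 0 else 1.0
        hits.append(MotifHit(peak_id, pwm.name, off, strand, score,
                             float(min(1.0, rel)), L))
    return hits


# ---------------------------------------------------------------------------
# dinucleotide-preserving shuffle (Altschul–Erickson Euler-path construction)

def _dinuc_shuffle_core(seq: str, rng: np.random.Generator) -> str:
    """One shuffle of an ACGT string preserving all dinucleotide counts.

    Builds the dinucleotide multigraph, draws a random last-edge arborescence
    toward the terminal vertex (rejection sampling), permutes the remaining
    out-edges and walks the Euler path. First and last bases are preserved.
    """
    n = len(seq)
    if n <= 3:
        return seq
    if len(set(seq)) == 1:
        return seq
    edges: dict[str, list[str]] = {}
    for i in range(n - 1):
        edges.setdefault(seq[i], []).append(seq[i + 1])
    last = seq[-1]
    verts = list(edges)
    nonterminal = [v for v in verts if v != last]
    while True:
        last_edge = {
            v: edges[v][int(rng.integers(len(edges[v])))] for v in nonterminal
        }
        ok = True
        for v in nonterminal:
            cur, steps = v, 0
            while cur != last:
                cur = last_edge.get(cur)
                steps += 1
                if cur is None or steps > len(verts):
                    ok = False
                    break
            if not ok:
                break
        if ok:
            break
    walk_edges: dict[str, list[str]] = {}
    for v in verts:
        pool = list(edges[v])
        if v != last:
            pool.remove(last_edge[v])
        perm = rng.permutation(len(pool))
        ordered = [pool[int(i)] for i in perm]
        if v != last:
            ordered.append(last_edge[v])
        walk_edges[v] = ordered
    pos = {v: 0 for v in verts}
    out = [seq[0]]
    cur = seq[0]
    for _ in range(n - 1):
        nxt = walk_edges[cur][pos[cur]]
        pos[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def _split_on_non_acgt(seq: str) -> list[tuple[bool, str]]:
    """Segments of (is_acgt, run) covering the sequence."""
    segs: list[tuple[bool, str]] = []
    cur: list[str] = []
    cur_acgt: bool | None = None
    for ch in seq.upper():
        is_acgt = ch in _BASE_INDEX
        if cur_acgt is None or is_acgt == cur_acgt:
            cur.append(ch)
        else:
            segs.append((cur_acgt, "".join(cur)))
            cur = [ch]
        cur_acgt = is_acgt
    if cur:
        segs.append((bool(cur_acgt), "".join(cur)))
    return segs


def sequence_rng(seed: int, original_id: str) -> np.random.Generator:
    """Per-sequence RNG stream derived from (seed, id) so results do not
    depend on processing order."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(original_id.encode())])


def dinucleotide_shuffle(
    seq: str,
    n: int = 10,
    seed: int = 0,
    original_id: str | None = None,
) -> ShuffleSet:
    """``n`` independent dinucleotide-preserving shuffles of ``seq``.

    Every shuffle has the exact dinucleotide count vector (hence base counts
    and GC content) of the original, with first and last bases preserved.
    Letters outside ACGT are only tolerated as separators: each maximal ACGT
    run is shuffled independently and the separators stay in place.
    """
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    up = seq.upper()
    segs = _split_on_non_acgt(up)
    if not any(is_acgt for is_acgt, _ in segs):
        raise ValueError("sequence contains no ACGT bases")
    oid = original_id if original_id is not None else up
    rng = sequence_rng(seed, oid)
    shuffles = []
    for _ in range(n):
        parts = [
            _dinuc_shuffle_core(run, rng) if is_acgt else run
            for is_acgt, run in segs
        ]
        shuffles.append("".join(parts))
    return ShuffleSet(original_id or "", tuple(shuffles), seed)


def dinucleotide_counts(seq: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(seq) - 1):
        d = seq[i : i + 2]
        counts[d] = counts.get(d, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# co-occurrence classification and enrichment

def _distinct_sites(hits: Iterable[MotifHit]) -> set[tuple[int, str]]:
    """Merge hits from multiple PWMs of one TF class: a site is a distinct
    (offset, strand) pair."""
    return {(h.offset, h.strand) for h in hits}


def classify_peak(
    sox_hits: Sequence[MotifHit],
    tcf_hits: Sequence[MotifHit],
    peak_id: str | None = None,
) -> PeakMotifClass:
    """Label one peak from its Sox and Tcf hit lists.

    Hits from different PWMs of the same class starting at the same offset
    and strand count once.
    """
    if peak_id is None:
        for h in list(sox_hits) + list(tcf_hits):
            peak_id = h.peak_id
            break
        else:
            peak_id = ""
    n_sox = len(_distinct_sites(sox_hits))
    n_tcf = len(_distinct_sites(tcf_hits))
    return PeakMotifClass(peak_id, _label_for(n_sox, n_tcf), n_sox, n_tcf)


def classify_window(
    seq: str,
    sox_pwms: Sequence[PWM],
    tcf_pwms: Sequence[PWM],
    rel_threshold: float = 0.70,
    peak_id: str = "",
    background: Sequence[float] | None = None,
) -> tuple[PeakMotifClass, list[MotifHit], list[MotifHit]]:
    """Scan one window with both PWM libraries and classify it."""
    sox_hits = [
        h for p in sox_pwms for h in scan_sequence(seq, p, rel_threshold, background, peak_id)
    ]
    tcf_hits = [
        h for p in tcf_pwms for h in scan_sequence(seq, p, rel_threshold, background, peak_id)
    ]
    return classify_peak(sox_hits, tcf_hits, peak_id), sox_hits, tcf_hits


def motif_class_enrichment(
    real: Sequence[PeakMotifClass],
    background: Sequence[PeakMotifClass],
    label: str,
) -> EnrichmentResult:
    """One-sided Fisher test of label frequency in real peaks vs background.

    The background rows are the classifications of the shuffled windows, each
    shuffle counted as an independent background sequence.
    """
    if not real:
        raise ValueError("real peak set is empty")
    a = sum(1 for c in real if c.label == label)
    b = len(real) - a
    c = sum(1 for cls in background if cls.label == label)
    d = len(background) - c
    table = ContingencyTable2x2(a, b, c, d)
    return EnrichmentResult(label, a, b, c, d, table.odds_ratio,
                            fisher_exact(table, "greater"))


@dataclass(frozen=True)
class SpacingResult:
    min_center_distance: float | None
    clustered_within: bool


def motif_spacing(
    sox_hits: Sequence[MotifHit],
    tcf_hits: Sequence[MotifHit],
    cluster_bp: float = 50,
) -> SpacingResult:
    """Minimum Sox-to-Tcf site-center distance and a <=50 bp clustering flag.

    With either class empty the distance is undefined and the flag false.
    """
    if not sox_hits or not tcf_hits:
        return SpacingResult(None, False)
    dist = min(abs(s.center - t.center) for s in sox_hits for t in tcf_hits)
    return SpacingResult(dist, dist <= cluster_bp)


@dataclass(frozen=True)
class MotifCountSummary:
    histogram: dict[int, int]
    fraction_above: float | None
    background_fraction_above: float | None = None


def motif_count_summary(
    classes: Sequence[PeakMotifClass],
    threshold: int = 5,
    background: Sequence[PeakMotifClass] | None = None,
) -> MotifCountSummary:
    """Histogram of Sox sites per peak and the fraction with > ``threshold``.

    An empty class list gives an empty histogram and an undefined fraction.
    When a background list is supplied its companion fraction is reported for
    comparison.
    """
    hist: dict[int, int] = {}
    for c in classes:
        hist[c.n_sox_sites] = hist.get(c.n_sox_sites, 0) + 1
    frac = (
        sum(1 for c in classes if c.n_sox_sites > threshold) / len(classes)
        if classes
        else None
    )
    bg_frac = None
    if background is not None and background:
        bg_frac = sum(1 for c in background if c.n_sox_sites > threshold) / len(background)
    return MotifCountSummary(hist, frac, bg_frac)
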