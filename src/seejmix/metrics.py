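"""Evaluation of reconstructed transcript segments against a reference.

A transcript segment (a SEEJ, or any method's output) is a set of
junctions. A computed junction matches a reference transcript when both its
donor and acceptor sites are within a tolerance (default 6 bp) of a
reference junction's sites. Two partial homogeneity scores compare a
segment to its best reference transcript: ``s_phs`` normalizes the matched
count by the segment length (favoring short, accurate segments) and
``s_hat_phs`` by the reference transcript length (favoring full-length
reconstruction). Precision/recall/F label individual junctions: TP/FP
against the segment's best-matching reference, FN for reference junctions
missed by every computed segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .junctions import Junction

DEFAULT_TOL = 6


@dataclass(frozen=True)
class TranscriptSegment:
    """A computed transcript segment: a set of junctions plus a source
    label. Junction sets produced by this package are valid SEEJs; external
    segments may be arbitrary."""

    junctions: frozenset[Junction]
    label: str = ""


@dataclass
class ReferenceSet:
    """Reference transcripts, each a junction set (e.g. from annotation
    exon chains)."""

    transcripts: dict[str, frozenset[Junction]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError("reference set must be non-empty")

    @property
    def all_junctions(self) -> frozenset[Junction]:
        out: set[Junction] = set()
        for t in self.transcripts.values():
            out |= t
        return frozenset(out)


def junction_matches(e: Junction, transcript, tol: int = DEFAULT_TOL) -> bool:
    """True iff some reference junction in ``transcript`` has both donor and
    acceptor within ``tol`` bases of ``e``'s (same chromosome required)."""
    for ref in transcript:
        if ref.chrom == e.chrom \
                and abs(e.start - ref.start) <= tol \
                and abs(e.end - ref.end) <= tol:
            return True
    return False


def _match_count(segment, transcript, tol: int) -> int:
    return sum(junction_matches(e, transcript, tol) for e in segment)


def phs_scores(segment, reference: ReferenceSet, tol: int = DEFAULT_TOL
               ) -> tuple[float, float, float]:
    """(s_phs, s_hat_phs, harmonic mean) of a segment against the reference.

    ``s_phs = max_T matched(T) / |segment|``;
    ``s_hat_phs = max_T matched(T) / |T|``; the harmonic mean is 0 when
    either score is 0. An empty segment is undefined (returns NaNs).
    """
    segment = set(segment)
    if not segment:
        return (float("nan"),) * 3
    s = max(_match_count(segment, T, tol) / len(segment)
            for T in reference.transcripts.values())
    s_hat = max(_match_count(segment, T, tol) / len(T)
                for T in reference.transcripts.values() if len(T) > 0)
    hm = 0.0 if s == 0 or s_hat == 0 else 2 * s * s_hat / (s + s_hat)
    return s, s_hat, hm


def average_scores(segments, reference: ReferenceSet, tol: int = DEFAULT_TOL
                   ) -> tuple[float, float, float]:
    """Arithmetic means of per-segment (s_phs, s_hat_phs, harmonic mean)."""
    if not segments:
        raise ValueError("need at least one segment")
    scores = np.array([phs_scores(seg, reference, tol) for seg in segments])
    return tuple(scores.mean(axis=0))


def _best_reference(segment, reference: ReferenceSet, score: str, tol: int
                    ) -> str:
    """Argmax reference id; ties prefer more matched junctions, then the
    lexicographically smallest id."""
    best = None
    for tid in sorted(reference.transcripts):
        T = reference.transcripts[tid]
        matched = _match_count(segment, T, tol)
        denom = len(segment) if score == "s_phs" else len(T)
        val = matched / denom if denom else 0.0
        key = (val, matched, tid)
        if best is None or (key[0], key[1]) > (best[0], best[1]):
            best = (val, matched, tid)
    return best[2]


def label_and_prf(segments, reference: ReferenceSet, score: str = "s_phs",
                  beta_values=(0.5, 1.0, 2.0), tol: int = DEFAULT_TOL) -> dict:
    """Junction-level precision/recall/F against best-matching references.

    Each segment is matched to its argmax reference T*; its junctions are TP
    if they match T* (within tolerance) and FP otherwise. Unique reference
    junctions not matched by any computed junction in any segment are FN.
    """
    if score not in ("s_phs", "s_hat"):
        raise ValueError("score must be 's_phs' or 's_hat'")
    tp = fp = 0
    computed_all: list[Junction] = []
    for seg in segments:
        seg = set(seg)
        computed_all.extend(seg)
        if not seg:
            continue
        t_star = reference.transcripts[_best_reference(seg, reference, score, tol)]
        for e in seg:
            if junction_matches(e, t_star, tol):
                tp += 1
            else:
                fp += 1
    fn = sum(
        not junction_matches(ref_j, computed_all, tol)
        for ref_j in reference.all_junctions
    )
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    out = {"tp": tp, "fp": fp, "fn": fn,
           "precision": precision, "recall": recall}
    for b in beta_values:
        denom = b * b * precision + recall
        out[f"f{b:g}"] = ((1 + b * b) * precision * recall / denom
                          if denom and np.isfinite(denom) else 0.0)
    return out


def filter_expressed_seejs(count_matrix: np.ndarray, min_reads: int = 10,
                           min_samples: int = 10) -> np.ndarray:
    """Indices of SEEJs expressed in enough samples.

    SEEJ k is expressed in sample i if at least ``min_reads`` tokens are
    assigned to it there; keep k iff that holds in at least ``min_samples``
    samples.
    """
    Y = np.asarray(count_matrix)
    expressed_in = (Y >= min_reads).sum(axis=0)
    return np.flatnonzero(expressed_in >= min_samples)


def classify_novelty(segments, reference: ReferenceSet, tol: int = DEFAULT_TOL
                     ) -> tuple[list[str], dict[Junction, str]]:
    """Label segments and junctions as known or novel.

    A segment is known iff a single reference transcript contains (within
    the per-junction tolerance) every one of its junctions; a junction is
    known iff it matches any reference junction.
    """
    seg_labels = []
    for seg in segments:
        seg = set(seg)
        known = any(
            all(junction_matches(e, T, tol) for e in seg)
            for T in reference.transcripts.values()
        ) if seg else True
        seg_labels.append("known" if known else "novel")
    junc_labels: dict[Junction, str] = {}
    universe = reference.all_junctions
    for seg in segments:
        for e in seg:
            if e not in junc_labels:
                junc_labels[e] = ("known" if junction_matches(e, universe, tol)
                                  else "novel")
    return seg_labels, junc_labels


def reference_from_gtf(path, tol_dedupe: bool = True) -> ReferenceSet:
    """Build a ReferenceSet from a GTF: each transcript's junctions are the
    introns between its consecutive exons (GTF 1-based inclusive exons are
    converted to 0-based half-open introns)."""
    from .junctions import _gtf_attr

    exons: dict[str, list[tuple[str, int, int, str]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            tid = _gtf_attr(f[8], "transcript_id") or "?"
            strand = f[6] if f[6] in ("+", "-") else "."
            exons.setdefault(tid, []).append((f[0], int(f[3]) - 1, int(f[4]), strand))
    transcripts: dict[str, frozenset[Junction]] = {}
    for tid, ex in exons.items():
        ex.sort(key=lambda e: (e[0], e[1]))
        juncs = set()
        for (c1, _, end1, strand), (c2, start2, _, _) in zip(ex, ex[1:]):
            if c1 == c2 and start2 > end1:
                juncs.add(Junction(c1, end1, start2, strand))
        if juncs:
            transcripts[tid] = frozenset(juncs)
    return ReferenceSet(transcripts)
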