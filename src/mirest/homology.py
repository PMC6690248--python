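"""Homology screening of ESTs against reference mature miRNAs.

Replaces the BLASTn step of the classic EST-mining protocol with an
exact mismatch-bounded scan: for every (reference, EST, strand) the
best window within the mismatch budget is reported.  With indels
allowed, a banded edit-distance search (edlib, infix mode) is used and
gap columns count against the same 0-4 budget, matching how the
reference tables book-keep gapped matures.

Redundant ESTs ("single tone" creation) are collapsed per reference
family, and putative protein-coding sequences are removed with a local
six-frame ORF-length heuristic standing in for a protein-database
search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import edlib
import numpy as np

from .sequence_io import SequenceRecord, reverse_complement

__all__ = [
    "HomologyHit",
    "OrfScanResult",
    "search_homologs",
    "brute_force_hits",
    "dedupe_single_tone",
    "filter_coding",
    "longest_orf",
]

MIN_REF_LEN = 15


@dataclass
class HomologyHit:
    """A reference mature matched on an EST within the mismatch budget.

    Coordinates are 1-based inclusive on the forward EST strand; for
    strand '-', ``matched_seq`` is the reverse complement of the forward
    window (i.e. the candidate mature read 5'->3').
    """

    ref_id: str
    est_id: str
    strand: str
    est_start: int
    est_end: int
    n_mismatch: int
    n_indel: int
    matched_seq: str

    @property
    def distance(self) -> int:
        return self.n_mismatch + self.n_indel

    @property
    def span(self) -> tuple:
        return (self.est_start, self.est_end)


def _enc(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _best_hamming_window(ref: np.ndarray, est: np.ndarray):
    """(best_start0, mismatches) of *ref* slid along *est*; leftmost tie wins."""
    m, n = ref.size, est.size
    if n < m:
        return None
    windows = np.lib.stride_tricks.sliding_window_view(est, m)
    mism = (windows != ref).sum(axis=1)
    i = int(mism.argmin())          # argmin takes the leftmost minimum
    return i, int(mism[i])


def _best_edlib_window(ref: str, est: str, k: int):
    """Best banded gapped alignment of *ref* inside *est* (infix mode)."""
    res = edlib.align(ref, est, mode="HW", task="path", k=k)
    if res["editDistance"] < 0:
        return None
    start0, end0 = res["locations"][0]
    cigar = res["cigar"] or ""
    n_sub = n_indel = 0
    num = ""
    for c in cigar:
        if c.isdigit():
            num += c
        else:
            cnt = int(num)
            num = ""
            if c == "X":
                n_sub += cnt
            elif c in "DI":
                n_indel += cnt
    return start0, end0, n_sub, n_indel


def search_homologs(refs, ests, max_mismatch: int = 4,
                    allow_indels: bool = True) -> list:
    """Scan every EST on both strands for each reference mature.

    For each (ref, est, strand) the best-scoring window is reported iff
    substitutions + gap columns <= *max_mismatch*; ties break to the
    leftmost start, and when both strands tie, to '+'.  References
    shorter than 15 nt are skipped with a warning (they cannot satisfy
    the downstream pairing criteria).
    """
    hits = []
    usable = []
    for ref in refs:
        if len(ref.residues) < MIN_REF_LEN:
            warnings.warn(f"reference {ref.id} shorter than {MIN_REF_LEN} nt; skipped",
                          stacklevel=2)
            continue
        usable.append(ref)
    for est in ests:
        fwd = est.residues
        rev = reverse_complement(fwd)
        n = len(fwd)
        fwd_e, rev_e = _enc(fwd), _enc(rev)
        for ref in usable:
            rseq = ref.residues
            m = len(rseq)
            best = None  # (distance, start, strand_rank, hit)
            for strand, est_seq, est_enc in (("+", fwd, fwd_e), ("-", rev, rev_e)):
                if allow_indels:
                    found = _best_edlib_window(rseq, est_seq, max_mismatch)
                    if found is None:
                        continue
                    s0, e0, n_sub, n_indel = found
                else:
                    found = _best_hamming_window(_enc(rseq), est_enc)
                    if found is None or found[1] > max_mismatch:
                        continue
                    s0, n_sub, n_indel = found[0], found[1], 0
                    e0 = s0 + m - 1
                if strand == "+":
                    start, end = s0 + 1, e0 + 1
                else:  # map back to forward coordinates
                    start, end = n - e0, n - s0
                matched = est_seq[s0:e0 + 1]
                cand = (n_sub + n_indel, start, 0 if strand == "+" else 1)
                if best is None or cand < best[0]:
                    best = (cand, HomologyHit(ref.id, est.id, strand, start, end,
                                              n_sub, n_indel, matched))
            if best is not None and best[0][0] <= max_mismatch:
                hits.append(best[1])
    return hits


def brute_force_hits(refs, ests, max_mismatch: int = 4) -> list:
    """Independent all-windows Hamming oracle (ungapped, both strands).

    Pure-python sliding scan used to verify :func:`search_homologs`
    with ``allow_indels=False``.
    """
    hits = []
    for est in ests:
        fwd = est.residues
        rev = reverse_complement(fwd)
        n = len(fwd)
        for ref in refs:
            r = ref.residues
            m = len(r)
            if m < MIN_REF_LEN or n < m:
                continue
            best = None
            for strand, s in (("+", fwd), ("-", rev)):
                for i in range(n - m + 1):
                    d = sum(a != b for a, b in zip(r, s[i:i + m]))
                    if strand == "+":
                        start, end = i + 1, i + m
                    else:
                        start, end = n - (i + m) + 1, n - i
                    cand = (d, start, 0 if strand == "+" else 1)
                    if best is None or cand < best[0]:
                        best = (cand, HomologyHit(ref.id, est.id, strand, start,
                                                  end, d, 0, s[i:i + m]))
            if best is not None and best[0][0] <= max_mismatch:
                hits.append(best[1])
    return hits


# --------------------------------------------------------------------------
# single-tone EST creation
# --------------------------------------------------------------------------

def _regional_identity(a: str, b: str) -> float:
    # containment identity: the shorter region aligned inside the longer,
    # so trimmed EST copies still count as identical around the hit
    if len(a) > len(b):
        a, b = b, a
    d = edlib.align(a, b, mode="HW", task="distance")["editDistance"]
    return 1.0 - d / len(a)


def dedupe_single_tone(hits, ests, identity_threshold: float = 0.95,
                       context: int = 100) -> list:
    """Collapse redundant ESTs to one representative per reference family.

    Within a family, ESTs whose hit-spanning regions (hit extended by
    *context* nt each side) are mutually identical above
    *identity_threshold* form one group; the longest EST represents the
    group (ties to the lexicographically smallest accession).
    Idempotent by construction.
    """
    seq_of = {e.id: e.residues for e in ests}
    by_family = {}
    for h in hits:
        by_family.setdefault(h.ref_id, []).append(h)
    kept = []
    for fam_hits in by_family.values():
        regions = {}
        for h in fam_hits:
            s = seq_of[h.est_id]
            lo = max(0, h.est_start - 1 - context)
            hi = min(len(s), h.est_end + context)
            regions[h.est_id] = s[lo:hi]
        ids = sorted(regions)
        parent = {i: i for i in ids}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if _regional_identity(regions[a], regions[b]) >= identity_threshold:
                    parent[find(a)] = find(b)
        groups = {}
        for i in ids:
            groups.setdefault(find(i), []).append(i)
        for members in groups.values():
            rep = min(members, key=lambda i: (-len(seq_of[i]), i))
            kept.extend(h for h in fam_hits if h.est_id == rep)
    return kept


# --------------------------------------------------------------------------
# coding filter
# --------------------------------------------------------------------------

@dataclass
class OrfScanResult:
    est_id: str
    longest_orf_codons: int
    frame: int               # 1..3 forward, 4..6 reverse
    is_coding: bool


_STOPS = {"UAA", "UAG", "UGA"}


def longest_orf(seq: str) -> tuple:
    """(codons, frame) of the longest ORF over all six frames.

    An ORF starts at AUG and runs to a stop codon or to the end of the
    frame (ESTs are fragments, so open-ended ORFs count).  The stop
    codon is not included in the codon count.
    """
    best, best_frame = 0, 1
    for frame_base, s in ((0, seq), (3, reverse_complement(seq))):
        for off in range(3):
            codons = [s[i:i + 3] for i in range(off, len(s) - 2, 3)]
            run = None
            for c in codons:
                if run is None:
                    if c == "AUG":
                        run = 1
                elif c in _STOPS:
                    if run > best:
                        best, best_frame = run, frame_base + off + 1
                    run = None
                else:
                    run += 1
            if run is not None and run > best:
                best, best_frame = run, frame_base + off + 1
    return best, best_frame


def filter_coding(candidates, min_orf_codons: int = 100):
    """Split candidate ESTs into (non-coding survivors, scan results).

    A record whose longest six-frame ORF reaches *min_orf_codons* codons
    is classified coding and removed — a deliberate local proxy for a
    protein-database similarity search.
    """
    noncoding, results = [], []
    for rec in candidates:
        codons, frame = longest_orf(rec.residues)
        coding = codons >= min_orf_codons
        results.append(OrfScanResult(rec.id, codons, frame, coding))
        if not coding:
            noncoding.append(rec)
    return noncoding, results
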