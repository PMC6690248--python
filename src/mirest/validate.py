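"""Screening criteria, characterization summaries, and cluster calls.

A folded candidate precursor passes when its hairpin is stable enough
(MFE at most -18 kcal/mol, or no worse than the reference hairpin when
reference-relative relaxation is enabled), the mature:star duplex holds
at least 16 Watson-Crick/G:U pairs (again relaxable to the reference),
the mature sits in the stem, the homology distance stays within 0-4,
and the source EST is non-coding.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

from .sequence_io import AnnotationRow, gc_content

__all__ = [
    "ValidationCriteria",
    "ValidationReport",
    "ClusterCall",
    "validate_candidate",
    "characterize",
    "detect_clusters",
    "detect_fixture_clusters",
]


@dataclass
class ValidationCriteria:
    """Tunable screening thresholds (defaults follow the protocol)."""

    mfe_max: float = -18.0            # kcal/mol
    min_pairs: int = 16               # mature:star WC/GU pairs
    max_mismatch: int = 4
    allow_reference_relaxation: bool = True
    forbid_large_loop: int = 6        # max bulge/loop run inside the mature

    def __post_init__(self):
        if self.mfe_max >= 0:
            raise ValueError("mfe_max must be negative")
        if self.min_pairs < 1:
            raise ValueError("min_pairs must be >= 1")


@dataclass
class ValidationReport:
    candidate_id: str
    mfe_ok: bool
    pairs_ok: bool
    in_stem: bool
    mismatch_ok: bool
    noncoding_ok: bool
    relaxation_used: bool = False

    @property
    def accepted(self) -> bool:
        return (self.mfe_ok and self.pairs_ok and self.in_stem
                and self.mismatch_ok and self.noncoding_ok)

    @property
    def flags(self) -> dict:
        return {
            "mfe_ok": self.mfe_ok,
            "pairs_ok": self.pairs_ok,
            "in_stem": self.in_stem,
            "mismatch_ok": self.mismatch_ok,
            "noncoding_ok": self.noncoding_ok,
        }


@dataclass
class ReferenceInfo:
    """What is known about the reference miRNA for relaxation purposes."""

    ref_id: str
    mfe: float | None = None
    star_pairs: int | None = None


def validate_candidate(candidate_id: str, mfe: float, metrics, n_distance: int,
                       noncoding: bool, reference=None,
                       criteria: ValidationCriteria | None = None) -> ValidationReport:
    """Evaluate every screening flag independently.

    *metrics* is a :class:`~mirest.fold.HairpinMetrics`; *n_distance* is
    the homology distance (substitutions + gap columns).  When an
    absolute threshold fails but the reference-relative comparison
    passes (and relaxation is enabled), the flag is granted and
    ``relaxation_used`` records it.
    """
    import warnings

    criteria = criteria or ValidationCriteria()
    relaxed = False

    mfe_ok = mfe <= criteria.mfe_max
    if not mfe_ok and criteria.allow_reference_relaxation:
        if reference is not None and reference.mfe is not None:
            if mfe <= reference.mfe:
                mfe_ok, relaxed = True, True
        else:
            warnings.warn(f"{candidate_id}: no reference MFE; relaxation skipped",
                          stacklevel=2)

    pairs_ok = metrics.mature_star_pairs >= criteria.min_pairs
    if not pairs_ok and criteria.allow_reference_relaxation:
        if reference is not None and reference.star_pairs is not None:
            if metrics.mature_star_pairs >= reference.star_pairs:
                pairs_ok, relaxed = True, True

    in_stem = bool(metrics.in_stem
                   and metrics.largest_asymmetry <= criteria.forbid_large_loop)
    mismatch_ok = 0 <= n_distance <= criteria.max_mismatch

    return ValidationReport(candidate_id, mfe_ok, pairs_ok, in_stem,
                            mismatch_ok, noncoding, relaxation_used=relaxed)


# --------------------------------------------------------------------------
# characterization
# --------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _bins(values, edges):
    out = {}
    for lo, hi in zip(edges[:-1], edges[1:]):
        out[f"{lo}-{hi}"] = sum(1 for v in values if lo <= v < hi)
    return out


def characterize(rows: list) -> dict:
    """Distribution summaries over accepted annotation rows.

    Mature-level statistics (length, mismatches, GC, arm, strand, organ)
    are over all rows; precursor-level statistics (length, MFE) are over
    distinct precursor records keyed by (source EST, length, MFE), since
    a clustered precursor contributes two matures but one hairpin.
    """
    if not rows:
        raise ValueError("characterize needs at least one row")
    mls = [r.mature_length for r in rows]
    nms = [r.n_mismatch for r in rows]
    gcs = [r.gc_percent for r in rows]
    precursors = sorted({(r.source_est, r.precursor_length, r.mfe) for r in rows})
    pls = [p[1] for p in precursors]
    mfes = [p[2] for p in precursors]

    def stats(v):
        mean = sum(v) / len(v)
        return {"min": min(v), "max": max(v), "mean": mean,
                "mean_rounded": _round_half_up(mean)}

    return {
        "n_matures": len(rows),
        "n_precursors": len(precursors),
        "precursor_length": stats(pls),
        "precursor_length_bins": _bins(pls, [0, 100, 200, 300, 400, 500]),
        "mfe": stats(mfes),
        "mfe_bins": _bins(mfes, [-150, -100, -50, 0]),
        "mature_length": stats(mls),
        "mature_length_hist": dict(sorted(Counter(mls).items())),
        "mismatches": stats(nms),
        "mismatch_hist": dict(sorted(Counter(nms).items())),
        "gc_percent": stats(gcs),
        "gc_bins": _bins(gcs, [0, 20, 40, 60, 80, 100]),
        "arm_counts": dict(sorted(Counter(r.arm for r in rows).items())),
        "strand_counts": dict(sorted(Counter(r.strand for r in rows).items())),
        "organ_counts": dict(sorted(Counter(r.organ for r in rows).items())),
    }


# --------------------------------------------------------------------------
# cluster detection
# --------------------------------------------------------------------------

@dataclass
class ClusterCall:
    precursor_id: str
    mature_spans: list = field(default_factory=list)
    is_cluster: bool = False
    notes: list = field(default_factory=list)


def _overlap(a, b) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def detect_clusters(spans_by_precursor: dict) -> list:
    """Call polycistronic precursors: >= 2 non-overlapping accepted matures.

    Overlapping mature spans on one precursor are merged into a single
    span (with a note) — two reference families matching the same EST
    region are one mature, not a cluster.
    """
    calls = []
    for pid, spans in sorted(spans_by_precursor.items()):
        merged, notes = [], []
        for span in sorted(spans):
            if merged and _overlap(merged[-1], span):
                old = merged[-1]
                merged[-1] = (min(old[0], span[0]), max(old[1], span[1]))
                notes.append(f"overlapping matures {old} and {span} merged")
            else:
                merged.append(tuple(span))
        calls.append(ClusterCall(pid, merged, len(merged) >= 2, notes))
    return calls


def detect_fixture_clusters(rows: list) -> list:
    """Cluster calls from annotation rows that carry no coordinates.

    Rows sharing one precursor record are co-resident matures; two rows
    with identical mature sequence and arm necessarily occupy the same
    span (overlap), while distinct (sequence, arm) pairs are distinct
    non-overlapping matures.  Reported per family stem so the clustered
    family appears once.
    """
    by_prec = {}
    for r in rows:
        key = (r.source_est, r.precursor_length, r.mfe)
        by_prec.setdefault(key, []).append(r)
    calls = []
    for key, group in sorted(by_prec.items()):
        distinct = {(r.mature_seq, r.arm) for r in group}
        fam = _family_stem(group[0].family)
        call = ClusterCall(precursor_id=f"{fam}@{key[0]}",
                           mature_spans=[],
                           is_cluster=len(distinct) >= 2)
        if len(group) > len(distinct):
            call.notes.append("identical matures from multiple families merged")
        calls.append(call)
    return calls


def _family_stem(family: str) -> str:
    return family.rstrip("abcdefgh")
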