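"""Synthetic EST corpora, reference sets, and transcriptomes with
planted ground truth.

Every generated feature (homolog, hairpin, coding decoy, duplicate
group, target site) is recorded in a :class:`TruthManifest`, so each
pipeline stage can be tested for exact recall/rejection without any
external download.  Generation is fully reproducible from a seed.

Designed-pass and designed-fail features are *verified at construction
time* (by rejection sampling against the package's own scoring) so the
manifest is guaranteed two-sided: pass features really satisfy the
criteria, fail features really violate exactly the intended one.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .homology import longest_orf
from .sequence_io import SequenceRecord, reverse_complement
from .targets import evaluate_duplex

__all__ = [
    "TruthManifest",
    "random_seq",
    "make_random_matures",
    "make_synthetic_precursor",
    "make_pair_limited_precursor",
    "make_synthetic_est_corpus",
    "make_synthetic_transcriptome",
]

_BASES = np.array(list("ACGU"))

# bases that can pair (WC or G:U) with each base
_PARTNERS = {"A": {"U"}, "C": {"G"}, "G": {"C", "U"}, "U": {"A", "G"}}


@dataclass
class TruthManifest:
    """Ground truth for one synthetic dataset (JSON round-trippable)."""

    seed: int
    planted_homologs: list = field(default_factory=list)
    planted_hairpins: list = field(default_factory=list)
    coding_decoys: list = field(default_factory=list)
    duplicate_groups: list = field(default_factory=list)
    planted_sites: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "TruthManifest":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        return cls(**d)


def random_seq(rng, n: int, gc_bias: float = 0.5) -> str:
    """Random RNA of length *n*; *gc_bias* is the total G+C probability."""
    p = np.array([(1 - gc_bias) / 2, gc_bias / 2, gc_bias / 2, (1 - gc_bias) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def make_random_matures(rng, n: int, length_range=(18, 26),
                        gc_bias: float = 0.5) -> list:
    """Reference-style mature miRNAs as SequenceRecords."""
    out = []
    for i in range(n):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        out.append(SequenceRecord(id=f"ref-mir{i+1:03d}",
                                  description=f"synthetic mature {i+1}",
                                  residues=random_seq(rng, L, gc_bias),
                                  alphabet_origin="RNA"))
    return out


def _mutate_non_pairing(base_to_avoid_pairing: str, current: str, rng) -> str:
    """A base that can pair with neither WC nor G:U against *base_to_avoid_pairing*."""
    options = [b for b in "ACGU"
               if b not in _PARTNERS[base_to_avoid_pairing] and b != current]
    return str(rng.choice(options))


def _substitute(seq: str, k: int, rng) -> str:
    """*k* substitutions at distinct positions, each to a different base."""
    pos = rng.choice(len(seq), size=k, replace=False)
    s = list(seq)
    for p in pos:
        s[p] = str(rng.choice([b for b in "ACGU" if b != s[p]]))
    return "".join(s)


def make_synthetic_precursor(mature: str, loop_len: int = 8,
                             star_mutations: int = 0, arm: str = "5'",
                             rng=None, pad: int = 10):
    """A foldable hairpin precursor with a planted mature.

    Layout (5' arm): pad + mature + loop + mutated-reverse-complement + pad;
    the 3' arm layout mirrors it.  Star mutations are substitutions that
    cannot pair (WC or G:U) with their mature partner, so the planted
    duplex offers ``len(mature) - star_mutations`` mature:star pairs; the
    minimum-energy fold realizes essentially all of them, though it may
    trade a single pair at a helix edge against the planted internal
    loop.  For a construct with a hard upper bound on pairing use
    :func:`make_pair_limited_precursor`.  Returns
    ``(precursor, truth_dict)`` with 1-based spans.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    L = len(mature)
    if not 18 <= L <= 26:
        raise ValueError(f"mature length {L} outside 18-26")
    if star_mutations >= L:
        raise ValueError("star_mutations must be < mature length")
    if loop_len < 3:
        raise ValueError("loop_len below the minimum hairpin loop")
    star = list(reverse_complement(mature))
    if star_mutations:
        # one contiguous block, kept clear of the helix ends, so the planted
        # structure is two long helices around a single internal loop and
        # the MFE fold retains every unmutated pair
        margin = min(3, (L - star_mutations) // 2)
        start = int(rng.integers(margin, L - star_mutations - margin + 1))
        for k in range(start, start + star_mutations):
            # star position k sits opposite mature position L-1-k; prefer a
            # base that cannot pair with the partner's neighbours either
            partner = L - 1 - k
            avoid = set(_PARTNERS[mature[partner]])
            for nb in (partner - 1, partner + 1):
                if 0 <= nb < L:
                    avoid |= _PARTNERS[mature[nb]]
            options = [b for b in "ACGU" if b not in avoid]
            if not options:
                options = [b for b in "ACGU"
                           if b not in _PARTNERS[mature[partner]]]
            star[k] = str(rng.choice(options))
    star = "".join(star)
    loop = "".join(rng.choice(np.array(list("AC")), size=loop_len))
    pad5 = random_seq(rng, pad)
    pad3 = random_seq(rng, pad)
    if arm == "5'":
        core = mature + loop + star
        mature_span = (pad + 1, pad + L)
    elif arm == "3'":
        core = star + loop + mature
        mature_span = (pad + L + loop_len + 1, pad + L + loop_len + L)
    else:
        raise ValueError(f"arm must be 5' or 3', got {arm!r}")
    precursor = pad5 + core + pad3
    truth = {
        "precursor_span": (1, len(precursor)),
        "mature_span": mature_span,
        "arm": arm,
        "star_mutations": int(star_mutations),
        "mature": mature,
    }
    return precursor, truth


def make_pair_limited_precursor(n_unpairable: int = 6, rng=None,
                                mature_len: int = 21, loop_len: int = 8,
                                pad: int = 10):
    """A hairpin whose mature:star pairing provably cannot exceed
    ``mature_len - n_unpairable``.

    The mature carries a central C-run of *n_unpairable* positions and no
    other C; the star's G partners are replaced by A, and the loop and
    padding are drawn G-free.  Since C pairs only G, the C-run can pair
    with nothing anywhere in the precursor, bounding the duplex above by
    construction (not merely by the folding engine's choice).  Flanks are
    G-rich so the remaining two helices keep the hairpin stable.
    Returns ``(precursor, truth_dict)``.
    """
    from .fold import fold_mfe  # local import: avoids cycle at module load

    rng = rng if rng is not None else np.random.default_rng(0)
    flank = mature_len - n_unpairable
    left, right = flank // 2, flank - flank // 2

    def seg(n):
        return "".join(rng.choice(np.array(list("AUG")), size=n,
                                  p=[0.15, 0.15, 0.7]))

    def gfree(n):
        return "".join(rng.choice(np.array(list("ACU")), size=n))

    loop = "A" * loop_len
    while True:  # construction-time stability check: the two flanking
        # helices must keep the hairpin clearly below the -18 threshold
        mature = seg(left) + "C" * n_unpairable + seg(right)
        star = "".join("A" if c == "G" else c
                       for c in reverse_complement(mature))
        precursor = gfree(pad) + mature + loop + star + gfree(pad)
        if fold_mfe(precursor).energy <= -20.0:
            break
    truth = {
        "precursor_span": (1, len(precursor)),
        "mature_span": (pad + 1, pad + mature_len),
        "arm": "5'",
        "max_star_pairs": mature_len - n_unpairable,
        "mature": mature,
    }
    return precursor, truth


def make_synthetic_est_corpus(refs, n_ests: int = 50, rng=None,
                              homolog_specs=None, hairpin_specs=None,
                              n_decoys: int = 0,
                              decoy_orf_codons: int = 120,
                              n_duplicates: int = 0,
                              length_range=(300, 900),
                              gc_bias: float = 0.5,
                              orf_threshold: int = 100):
    """An EST corpus with planted homologs, hairpins, decoys, duplicates.

    *homolog_specs* is a list of ``(ref_index, n_mismatch, strand)``;
    each spec plants one mutated copy of that reference into its own
    background EST.  *hairpin_specs* is a list of
    ``(ref_index, arm, star_mutations)``; each plants a full foldable
    precursor built around that reference mature (forward strand), so
    the EST survives the whole discovery funnel.  *n_decoys* ESTs carry
    an ORF of *decoy_orf_codons* codons.  *n_duplicates* extra
    near-copies of the first planted-homolog EST exercise single-tone
    deduplication.  Background ESTs are rejection-sampled to stay below
    *orf_threshold* codons so the coding truth is exact.

    Returns ``(records, manifest)``.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    homolog_specs = homolog_specs or []
    hairpin_specs = hairpin_specs or []
    manifest = TruthManifest(seed=-1)
    records = []

    def background(n):
        while True:
            s = random_seq(rng, n, gc_bias)
            if longest_orf(s)[0] < orf_threshold:
                return s

    est_no = 0

    def next_id():
        nonlocal est_no
        est_no += 1
        return f"EST{est_no:05d}"

    first_homolog_rec = None
    for ref_idx, n_mm, strand in homolog_specs:
        ref = refs[ref_idx]
        m = len(ref.residues)
        n = int(rng.integers(*length_range))
        host = background(n)
        insert = _substitute(ref.residues, n_mm, rng)
        if strand == "-":
            insert = reverse_complement(insert)
        pos = int(rng.integers(0, n - m + 1))
        seq = host[:pos] + insert + host[pos + m:]
        rec = SequenceRecord(id=next_id(), description=f"planted:{ref.id}",
                             residues=seq, alphabet_origin="RNA")
        records.append(rec)
        if first_homolog_rec is None:
            first_homolog_rec = rec
        manifest.planted_homologs.append({
            "ref_id": ref.id, "est_id": rec.id, "strand": strand,
            "span": (pos + 1, pos + m), "n_mismatch": int(n_mm),
        })

    for ref_idx, arm, star_muts in hairpin_specs:
        ref = refs[ref_idx]
        pre, truth = make_synthetic_precursor(ref.residues, loop_len=8,
                                              star_mutations=star_muts,
                                              arm=arm, rng=rng)
        n = max(int(rng.integers(*length_range)), len(pre) + 80)
        host = background(n)
        pos = int(rng.integers(40, n - len(pre) - 40 + 1))
        seq = host[:pos] + pre + host[pos + len(pre):]
        rec = SequenceRecord(id=next_id(), description=f"hairpin:{ref.id}",
                             residues=seq, alphabet_origin="RNA")
        records.append(rec)
        ms = (pos + truth["mature_span"][0], pos + truth["mature_span"][1])
        manifest.planted_hairpins.append({
            "est_id": rec.id, "ref_id": ref.id,
            "precursor_span": (pos + 1, pos + len(pre)),
            "mature_span": ms, "arm": arm,
            "star_mutations": int(star_muts),
        })
        manifest.planted_homologs.append({
            "ref_id": ref.id, "est_id": rec.id, "strand": "+",
            "span": ms, "n_mismatch": 0,
        })

    for _ in range(n_decoys):
        k = decoy_orf_codons
        codons = []
        while len(codons) < k - 1:
            c = random_seq(rng, 3)
            if c not in ("UAA", "UAG", "UGA"):
                codons.append(c)
        orf = "AUG" + "".join(codons) + "UAA"
        flank = max(10, (int(rng.integers(*length_range)) - len(orf)) // 2)
        seq = background(flank) + orf + background(flank)
        rec = SequenceRecord(id=next_id(), description="decoy:orf",
                             residues=seq, alphabet_origin="RNA")
        records.append(rec)
        manifest.coding_decoys.append({"est_id": rec.id, "orf_codons": int(k)})

    if n_duplicates and first_homolog_rec is not None:
        group = [first_homolog_rec.id]
        src = first_homolog_rec.residues
        entry = manifest.planted_homologs[0]
        a, b = entry["span"]
        for _ in range(n_duplicates):
            # trim random amounts clear of the planted span
            left = int(rng.integers(0, max(1, a - 1)))
            right = int(rng.integers(0, max(1, len(src) - b)))
            seq = src[left:len(src) - right]
            rec = SequenceRecord(id=next_id(), description="duplicate",
                                 residues=seq, alphabet_origin="RNA")
            records.append(rec)
            group.append(rec.id)
            manifest.planted_homologs.append({
                "ref_id": entry["ref_id"], "est_id": rec.id,
                "strand": entry["strand"],
                "span": (a - left, b - left), "n_mismatch": entry["n_mismatch"],
            })
        manifest.duplicate_groups.append(group)

    while len(records) < n_ests:
        rec = SequenceRecord(id=next_id(), description="background",
                             residues=background(int(rng.integers(*length_range))),
                             alphabet_origin="RNA")
        records.append(rec)
    return records, manifest


def make_synthetic_transcriptome(matures, site_specs, rng=None,
                                 n_transcripts: int = 20,
                                 length_range=(300, 800),
                                 energy_max: float = -20.0):
    """Transcripts with planted target sites of known classes.

    *site_specs* is a list of ``(mature_index, kind)`` with kind one of:

    - ``"pass"``: exact reverse complement of the mature (all-WC duplex),
      rejection-checked to reach *energy_max*;
    - ``"seed_broken"``: as pass, but the target bases opposite miRNA
      positions 3 and 10 are flipped to non-pairing bases, breaking both
      seed windows;
    - ``"energy_fail"``: an all-WC site for a synthetic A/U-only 18-nt
      mature, rejection-checked to miss *energy_max* (weak helix).

    Returns ``(records, manifest)``; background transcripts have no
    designed sites.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    manifest = TruthManifest(seed=-1)
    records = []
    tno = 0

    def next_id():
        nonlocal tno
        tno += 1
        return f"TR{tno:04d}"

    for mi, kind in site_specs:
        if kind == "energy_fail":
            while True:
                mature = random_seq(rng, 18, gc_bias=0.0)
                site = reverse_complement(mature)
                if evaluate_duplex(mature, site).hybrid_energy > energy_max:
                    break
            mirna_id = f"au-only-{tno+1}"
        else:
            rec = matures[mi]
            mirna_id = rec.id
            mature = rec.residues
            site = reverse_complement(mature)
            if evaluate_duplex(mature, site).hybrid_energy > energy_max:
                raise ValueError(f"mature {rec.id} too weak for a designed-pass site")
        L = len(mature)
        if kind == "seed_broken":
            s = list(site)
            for mpos in (3, 10):
                tpos = L - mpos  # 0-based index in site opposite miRNA pos mpos
                s[tpos] = _mutate_non_pairing(mature[mpos - 1], s[tpos], rng)
            site = "".join(s)
        n = int(rng.integers(*length_range))
        host = random_seq(rng, n)
        pos = int(rng.integers(0, n - L + 1))
        seq = host[:pos] + site + host[pos + L:]
        rec_t = SequenceRecord(id=next_id(), description=f"site:{kind}",
                               residues=seq, alphabet_origin="RNA")
        records.append(rec_t)
        manifest.planted_sites.append({
            "mirna": mirna_id, "mature": mature, "transcript_id": rec_t.id,
            "span": (pos + 1, pos + L), "seed_intact": kind != "seed_broken",
            "designed_energy_class": "fail" if kind == "energy_fail" else "pass",
        })
    while len(records) < n_transcripts:
        rec_t = SequenceRecord(id=next_id(), description="background",
                               residues=random_seq(rng, int(rng.integers(*length_range))),
                               alphabet_origin="RNA")
        records.append(rec_t)
    return records, manifest
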