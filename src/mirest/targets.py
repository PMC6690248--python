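"""miRNA target-site scanning, duplex evaluation, and categorization.

Sites are found by sliding the mature along the transcript in the
antiparallel register: position i from the miRNA 5' end pairs with
position L-i+1 of the site.  A site must cover at least 75% of the
miRNA with Watson-Crick or G:U pairs and stay within a penalty budget
(mismatch 1, G:U 0.5, cap 3.0 — a stand-in for a server-side
expectation score).  The duplex is then scored with the folding
module's stacking table (intermolecular helix; the target's own
structure is ignored, as in energy-only hybridization tools), and a
target is accepted when the hybrid energy is at most -20 kcal/mol, a
stringent seed (all-WC at miRNA positions 2-7 and/or 8-13) holds, and
at least 3 pairs support the 3' supplementary region (positions 17+).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .fold import EnergyModel, default_model, _PAIRS
from .sequence_io import canonical_category

__all__ = [
    "Duplex",
    "TargetCall",
    "scan_target_sites",
    "evaluate_duplex",
    "filter_targets",
    "categorize_function",
    "summarize_categories",
    "render_duplex",
]

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}

PENALTY_MISMATCH = 1.0
PENALTY_GU = 0.5
PENALTY_GAP = 2.0
PENALTY_MAX = 3.0


@dataclass
class Duplex:
    """An evaluated miRNA:site pairing (ungapped antiparallel register)."""

    mirna: str
    site: str
    site_span: tuple                 # 1-based on the transcript
    pair_string: str                 # per miRNA position: ':' WC, '.' GU, ' ' none
    n_paired: int                    # WC + GU
    seed_2_7: bool
    seed_8_13: bool
    supplementary_ok: bool
    hybrid_energy: float             # kcal/mol


@dataclass
class TargetCall:
    mirna_family: str
    target_id: str
    duplex: Duplex
    category: str = "Hypothetical protein"
    description: str = ""


def _pair_class(m: str, t: str) -> str:
    if (m, t) in _WC:
        return ":"
    if (m, t) in _GU:
        return "."
    return " "


def _register(mirna: str, site: str) -> str:
    """Pair symbols per miRNA 5'->3' position against the reversed site."""
    rev = site[::-1]
    return "".join(_pair_class(m, t) for m, t in zip(mirna, rev))


def scan_target_sites(mature: str, transcript: str,
                      min_coverage: float = 0.75,
                      penalty_max: float = PENALTY_MAX) -> list:
    """Candidate site spans (1-based, inclusive) on *transcript*.

    Every window of miRNA length is scored in the antiparallel register;
    windows pass when the paired fraction reaches *min_coverage* and the
    penalty score stays within *penalty_max*.  Overlapping passing
    windows are merged, keeping the best-scoring (then leftmost) one.
    """
    m = len(mature)
    n = len(transcript)
    if n < m:
        return []
    passing = []
    for i in range(n - m + 1):
        ps = _register(mature, transcript[i:i + m])
        paired = sum(c != " " for c in ps)
        if paired / m < min_coverage:
            continue
        penalty = PENALTY_MISMATCH * ps.count(" ") + PENALTY_GU * ps.count(".")
        if penalty > penalty_max:
            continue
        passing.append((penalty, i + 1, i + m))
    passing.sort(key=lambda t: (t[0], t[1]))
    chosen = []
    for pen, s, e in passing:
        if all(e < cs or s > ce for _, cs, ce in chosen):
            chosen.append((pen, s, e))
    return [(s, e) for _, s, e in sorted(chosen, key=lambda t: t[1])]


def evaluate_duplex(mature: str, site: str, site_span: tuple = None,
                    model: EnergyModel | None = None,
                    seed_allows_gu: bool = False,
                    supplementary_min_pairs: int = 3) -> Duplex:
    """Score one miRNA:site duplex in the antiparallel register.

    Seed windows (miRNA positions 2-7 and 8-13 from the 5' end) demand
    Watson-Crick pairs; G:U counts toward coverage and the supplementary
    region but, by default, not inside the seed.  The hybrid energy sums
    the stacking table over consecutive paired positions plus
    internal-loop penalties for mismatch interruptions.
    """
    if not site:
        raise ValueError("zero-length target site")
    model = model or default_model()
    ps = _register(mature, site)
    L = len(ps)
    seed_sym = (":", ".") if seed_allows_gu else (":",)

    def window_ok(lo, hi):  # 1-based miRNA positions, inclusive
        if hi > L:
            return False
        return all(ps[k - 1] in seed_sym for k in range(lo, hi + 1))

    n_paired = sum(c != " " for c in ps)
    supp = sum(1 for k in range(17, L + 1) if ps[k - 1] != " ")
    # short matures expose fewer than 3 positions beyond 16; the
    # requirement scales down to what the molecule can offer
    supp_required = max(0, min(supplementary_min_pairs, L - 16))
    energy = _hybrid_energy(mature, site, ps, model)
    return Duplex(
        mirna=mature,
        site=site,
        site_span=site_span or (1, len(site)),
        pair_string=ps,
        n_paired=n_paired,
        seed_2_7=window_ok(2, 7),
        seed_8_13=window_ok(8, 13),
        supplementary_ok=supp >= supp_required,
        hybrid_energy=energy,
    )


def _hybrid_energy(mature: str, site: str, ps: str, model: EnergyModel) -> float:
    """Stacks over consecutive pairs; mismatch runs cost an internal loop."""
    rev = site[::-1]
    pidx = {p: k for k, p in enumerate(_PAIRS)}
    total = 0
    prev = None          # index of previous paired position
    for k, c in enumerate(ps):
        if c == " ":
            continue
        if prev is not None:
            gap = k - prev - 1
            if gap == 0:
                total += model.stack[pidx[mature[prev] + rev[prev]],
                                     pidx[mature[k] + rev[k]]]
            else:
                total += model.internal_e(gap, gap)
        prev = k
    return total / 100.0


def filter_targets(duplexes, energy_max: float = -20.0,
                   require_seed: bool = True,
                   require_supplementary: bool = True) -> list:
    """Keep duplexes meeting the energy, seed, and supplementary rules.

    *duplexes* is an iterable of (family, target_id, Duplex[, description])
    tuples or TargetCall objects; accepted ones come back as TargetCalls.
    """
    accepted = []
    for item in duplexes:
        if isinstance(item, TargetCall):
            call = item
        else:
            fam, tid, dx = item[0], item[1], item[2]
            desc = item[3] if len(item) > 3 else ""
            call = TargetCall(fam, tid, dx, categorize_function(desc or "unknown"),
                              desc)
        dx = call.duplex
        if dx.hybrid_energy > energy_max:
            continue
        if require_seed and not (dx.seed_2_7 or dx.seed_8_13):
            continue
        if require_supplementary and not dx.supplementary_ok:
            continue
        accepted.append(call)
    return accepted


# --------------------------------------------------------------------------
# functional categorization
# --------------------------------------------------------------------------

# first-match keyword rules; order matters (signal-transduction kinases
# override the generic enzyme rule)
_KEYWORD_RULES = [
    ("Signal transduction",
     ["protein kinase", "snf1", "signal", "phosphatase 2c", "receptor",
      "pas sensor", "calcium dependent protein kinase", "pyruvate kinase",
      "phosphofructo"]),
    ("Stress related",
     ["heat shock", "stress", "salt-tolerance", "resistance", "jasmonate",
      "dnaj", "chaperone", "cold shock", "tir", "vancomycin", "groel",
      "cprd", "peroxidase"]),
    ("Transporter",
     ["transporter", "transport", "antiporter", "exchanger", "porin",
      "abc", "atp-binding cassette", "carrier", "vacuolar protein sorting",
      "nucleoporin", "sec24", "membrane protein"]),
    ("Transcription factor",
     ["transcription factor", "transcription", "myb", "zinc finger", "bzip",
      "homeobox", "homeodomain", "nac domain", "nam", "wrky", "leucine zipper",
      "scof", "tiny", "hmg", "tfiie", "rna polymerase", "ribonucleoprotein"]),
    ("Growth and development",
     ["ripening", "tumor", "growth", "septation", "acc oxidase"]),
    ("Structural protein",
     ["ribosomal protein", "structural", "glycine-rich"]),
    ("Disease related",
     ["disease", "multidrug", "glycoprotein"]),
    ("Metabolism",
     ["kinase", "phosphatase", "synthase", "synthetase", "oxidase",
      "esterase", "reductase", "transferase", "hydrolase", "dehydrogenase",
      "decarboxylase", "carboxylase", "oxidoreductase", "oxygenase",
      "glucanase", "protease", "proteinase", "isomerase", "ligase",
      "cytochrome", "gtpase", "atpase", "nuclease", "ribonuclease",
      "dioxygenase", "expansin", "metabol", "glycosyltransferase", "lipase",
      "amylase", "invertase", "enzyme"]),
]


def categorize_function(description: str) -> str:
    """Assign a functional category to a free-text product description."""
    if not description:
        raise ValueError("empty description")
    d = description.lower()
    for category, keywords in _KEYWORD_RULES:
        if any(k in d for k in keywords):
            return category
    return "Hypothetical protein"


def summarize_categories(calls) -> dict:
    """Counts and integer percentages per canonical category.

    *calls* may be TargetCalls, TargetRows (printed labels), or plain
    label strings; labels are canonicalized first.
    """
    labels = []
    for c in calls:
        if isinstance(c, str):
            labels.append(canonical_category(c))
        elif hasattr(c, "function_label"):
            labels.append(canonical_category(c.function_label))
        else:
            labels.append(canonical_category(c.category))
    if not labels:
        raise ValueError("no calls to summarize")
    counts = Counter(labels)
    total = len(labels)
    return {
        "total": total,
        "counts": dict(counts.most_common()),
        "percent": {k: round(100 * v / total) for k, v in counts.most_common()},
    }


def render_duplex(dx: Duplex) -> str:
    """Text rendering in the printed-table symbol convention
    (miRNA shown 3'->5' over the target site 5'->3')."""
    return (f"miRNA  3' {dx.mirna[::-1]} 5'\n"
            f"          {dx.pair_string[::-1]}\n"
            f"target 5' {dx.site} 3'  ({dx.site_span[0]}-{dx.site_span[1]})")
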