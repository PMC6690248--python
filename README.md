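# mirest

Homology-based discovery and validation of plant microRNAs from EST
collections — with hairpin folding, target prediction, and conservation
analysis — implemented as a tested, fully offline Python package.

## The problem

Most plant miRNA families are deeply conserved, so new family members in
a species with little genomic data can be found by screening its
expressed sequence tags (ESTs) against known mature miRNAs.  A credible
candidate must survive a funnel of filters: close homology to a known
mature (0–4 mismatches, either strand), a single representative EST per
family, no protein-coding signal, and a stable stem-loop precursor in
which the mature sits on one arm and pairs extensively with its star
(miRNA\*) partner.  Validated miRNAs are then characterized (length,
MFE, GC%, arm, strand), checked for polycistronic clusters, aligned
across species with an NJ cladogram, and matched to mRNA targets via
seed-site complementarity and duplex energetics.

`mirest` is aimed at researchers who want this classic pipeline as a
reproducible library rather than a chain of web servers.

## The core criteria

For a candidate precursor with structure energy ΔG and mature:star
pairing *p* (Watson–Crick + G:U):

- ΔG ≤ −18 kcal/mol, or ΔG ≤ ΔG(reference hairpin);
- *p* ≥ 16, or *p* ≥ p(reference);
- the mature lies in the stem, uninterrupted by large loops;
- homology distance ≤ 4 (substitutions + gap columns);
- the source EST is non-coding (longest six-frame ORF < 100 codons).

Targets require ≥ 75 % paired coverage, hybrid energy ≤ −20 kcal/mol, a
stringent all-WC seed at miRNA positions 2–7 and/or 8–13, and a
3′-supplementary site.  Folding uses an in-house Zuker-style dynamic
program over a nearest-neighbour model (stacking + loop penalties, G:U
wobble, integer centi-kcal energies); see `docs/methods.md` for every
model detail and deviation.

The package ships transcriptions of the source study's two reference
tables (46 characterized cowpea matures; 138 miRNA–target records) and
recomputes every derivable column from them.

## Worked example

Generate a synthetic EST corpus with three planted hairpin precursors
plus a coding decoy and background, then run the full funnel:

```python
import numpy as np
from mirest.sequence_io import write_fasta
from mirest.synthetic import make_random_matures, make_synthetic_est_corpus
from mirest.pipeline import PipelineConfig, run_pipeline

rng = np.random.default_rng(7)
refs = make_random_matures(rng, 3, length_range=(20, 22), gc_bias=0.55)
ests, truth = make_synthetic_est_corpus(
    refs, n_ests=12, rng=rng,
    hairpin_specs=[(0, "5'", 0), (1, "3'", 0), (2, "5'", 2)],
    n_decoys=1)
write_fasta(refs, "refs.fasta"); write_fasta(ests, "ests.fasta")

cfg = PipelineConfig(refs_fasta="refs.fasta", ests_fasta="ests.fasta",
                     out_dir="out", max_extension_nt=50)
report = run_pipeline(cfg)
print("\n".join(report["log"][1:]))
```

which prints the stage funnel:

```
stage=load refs=3 ests=12
stage=search in=12 hits=3
stage=dedupe hits=3
stage=coding_filter in=3 noncoding=3 hits=3
stage=validate folded=3 accepted=3
stage=clusters precursors=3 clusters=0
```

All three planted hairpins are recovered and accepted; the decoy and
background ESTs never reach the folding stage.  `out/candidates.tsv`
mirrors the discovery-table columns, e.g.

```
family          ref_id      precursor_length  mfe     mature_seq              ...  accepted
can-ref-mir001  ref-mir001  72                -39.40  TTCCTATTCCCCCGGTTGTAAG  ...  True
```

— a 72-nt excised precursor folding at −39.4 kcal/mol with the planted
mature fully paired to its star.  The same stages are available as CLI
subcommands (`mirest search|fold|targets|phylo|synth|run|check-fixtures`);
`mirest check-fixtures` recomputes the reference-table statistics
(GC%/length agreement 46/46, 138 target records, 37 Metabolism labels,
the single vun-mir4414 two-mature cluster) and lists the known printed
discrepancies it flags.

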