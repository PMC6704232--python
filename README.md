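# rnaikit

Design of long double-stranded RNAi triggers and prediction of their siRNA
off-targets.

In plants, fungi and invertebrates, long dsRNA is a practical trigger of
RNA interference: Dicer processes it into ~21-nt siRNAs, one strand of each
duplex is loaded into RISC, and transcripts complementary to that guide
strand are cleaved. Picking a good trigger region is therefore two problems
at once: *specificity* — which other transcripts share 21-mers with the
trigger and may be silenced unintentionally — and *efficiency* — which of
the trigger's siRNAs will actually be loaded and find an accessible target
site. `rnaikit` addresses both for anyone designing hairpin/RNAi constructs
against a custom transcript database (crop gene silencing, HIGS/VIGS,
gene-family knockdowns).

## What it computes

Given a trigger sequence and a FASTA transcript database, the pipeline:

1. **enumerates** all k-mer siRNA duplexes of the trigger (default k = 21;
   sense strand = trigger window, antisense strand = candidate guide);
2. **matches** both strands of every duplex against the database, exactly or
   with up to two mismatches (hash index + pigeonhole seed-and-verify;
   equivalent to a full Hamming scan);
3. **scores strand selection**: the guide is the strand with the less stable
   5′ end. End stability is the sum of nearest-neighbor stacking energies
   ΔG°37 over the terminal base pairs (default: first three nucleotides, two
   stacks, Xia/Turner values). With ΔMFE = ΔG(guide 5′) − ΔG(passenger 5′),
   the thermodynamic rule is ΔMFE > 0, the strict rule ΔMFE > 1 kcal/mol,
   and the sequence rule asks for 5′-terminal U/A on the guide;
4. **computes local accessibility**: the LAP profile — the Boltzmann
   probability P(stretch of u nt unpaired), from a McCaskill-style windowed
   partition function (defaults u = 8, span L = 40, window W = 80), averaged
   over all windows containing the stretch; a target site counts as
   accessible when its best stretch reaches the 0.1 threshold;
5. **classifies** every siRNA/transcript hit in two modes:
   *high-sensitivity* (HS, strand-selection rules only — for exhaustive
   off-target discovery) and *high-efficiency* (HE, strict strand rules AND
   site accessibility — for potent construct design), with HE ⊆ HS by
   construction;
6. **reports** per-position hit curves, green/red off-target zoning, a
   per-transcript ranking, and — in design mode — the best trigger region
   (default 100 nt) free of off-target zones.

A synthetic-construct generator (percent-randomized "molecular clock"
series and 100-nt window constructs embedded in randomized backbones)
provides realistic validation fixtures without any sequence download.

## Worked example

Build a 500-nt target and a 6%-diverged paralog (a realistic gene-family
situation), then run both modes:

```sh
rnaikit offtarget --trigger trigger.fasta --db db.fasta --out ot
# trigger target_gene: 639 total hits on 2 transcripts
#   target_gene   total=480  hs=337
#   paralog       total=159  hs=112
```

The trigger's 480 21-mers (500 − 21 + 1) all hit the target; 159 of them
also survive 6% divergence and hit the paralog — a serious off-target.
Design mode against the single intended target then refuses to recommend a
region, because paralog hits paint nearly the whole trigger red:

```sh
rnaikit design --trigger trigger.fasta --db db.fasta \
    --main-target target_gene --out ds
# trigger target_gene: 102 HE-mode hits
#   no recommendable region (no HE siRNA in a red-free window)
```

Declaring the whole family as intended targets resolves the conflict:

```sh
rnaikit design --trigger trigger.fasta --db db.fasta \
    --main-target target_gene --main-target paralog --out ds2
# trigger target_gene: 136 HE-mode hits
#   recommended region 36-135 (34 HE siRNAs)
```

i.e. the 100-nt window starting at position 36 contains 34 siRNAs that pass
the strict strand-selection rules and target accessible sites on an
intended transcript. Each run writes `hits.tsv`, `positions.tsv`,
`transcripts.tsv`, accessibility profiles, a JSON summary, a plot and the
resolved configuration into the output directory.

The packaged benchmark table of a published barley *Mlo* construct series
links predicted counts to measured silencing strength:

```sh
rnaikit evaluate
# total_hits   -0.31
# hs_hits      -0.37
# he_hits      -0.61
```

The HE-mode count correlates best with the observed silencing effect —
the rationale for using HE mode when choosing a construct region.

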