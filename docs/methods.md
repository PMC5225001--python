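# Methods

This note documents the statistical models, the synthetic study design,
the numerical conventions, and the open design choices behind `seednet`.

## Study design assumptions

The pipeline targets the common exploratory design in non-mammalian
toxicology: two conditions (vehicle control vs. exposure), **one
small-RNA library per condition**, single-end reads, a focal species whose
miRNA catalogue is incomplete, and a matched mRNA differential-expression
table from the same exposure available for integration. Nothing in the
package estimates biological variance — with n = 1 per group that is
impossible — so every "significant" call is a statement about sequencing
(counting) noise only, and downstream stages are designed to compensate by
intersecting independent evidence (mRNA anti-correlation, functional
enrichment).

## Read filtering and hierarchical mapping

Clean-read criteria, applied in order per read:

1. *quality*: discard when the fraction of bases with Phred < `q_threshold`
   (default 20) strictly exceeds `q_fraction` (default 0.30). Quality is
   judged on the full, untrimmed read.
2. *adapter*: truncate at the leftmost exact match of the adapter's first
   8 nt (default adapter: Truseq small-RNA 3' `TGGAATTCTCGGGTGCCAAGG`).
   A read emptied by trimming counts as adapter-only.
3. *length*: discard post-trim inserts shorter than `min_len` (default
   17 nt — also the minimum mapping overlap).

Mapping is exact substring containment in either direction (read in
mature sequence or mature in read) with overlap ≥ `min_len` and 0
mismatches by default; a `max_mismatches` knob (naive scan) exists for
degraded data. References are searched in species order (default
`dre, rno, mmu, hsa`) and the first species with a hit wins; within a
species ties break by longest overlap, then lexicographically smallest
miRNA id, making assignment deterministic and independent of read input
order. Assignments to a non-first species are tagged *cross-species*
("predicted") features. T/U are normalized to one alphabet at ingest.
A full Burrows–Wheeler aligner would add nothing at this problem scale
and would make the mapping rule harder to state exactly; exact containment
is unambiguous on references whose sequences share no 17-mer, which the
synthetic reference guarantees by construction.

No de-novo (hairpin-folding) miRNA discovery is attempted: the
"predicted miRNA" category is realized solely by cross-species mapping,
and reads matching no reference remain unmapped. A cross-species feature
is only allowed to carry a significant DE call when its mean expression
reaches `min_cpm` (default 10 CPM); low-count rescues from a foreign
database are otherwise too fragile to report.

## Unreplicated differential expression

For a feature with treated/control counts $x, y$ and library totals
$n_t, n_c$, conditioning on $m = x + y$ gives the exact null
$x \sim \mathrm{Bin}(m, p_0)$, $p_0 = n_t/(n_t + n_c)$ — the classic
two-Poisson-libraries argument. Two-sided p-values use the
minimum-likelihood rule: sum the probabilities of all outcomes no more
probable than the observed one, with outcomes within relative $10^{-12}$
of the observed probability counted as ties. The sum is normalized by the
total mass so that including every outcome returns exactly 1. Features
with $x = y = 0$ are untestable: they are reported with p = 1, excluded
from the BH family (untestable hypotheses would inflate the correction),
and can never be significant.

Fold change is treated/control on the CPM scale with a pseudocount of 0.5
added to both counts, which bounds log2 FC for zero counts. The
significance gate is strict: FC > 2 or FC < 0.5, **and** p < 0.05 **and**
BH-FDR < 0.05. FC orientation (treated/control) is a convention; swapping
the libraries maps FC to 1/FC and leaves p and FDR unchanged (tested).
The 2^-ΔΔCt utility mirrors how such calls are conventionally validated
by qPCR against a reference gene.

## Target prediction and anti-correlation

Site classes for a miRNA with 5' positions $1..n$ (seed = positions 2–8),
matched on the UTR sense strand:

| class   | pattern                                   | weight |
|---------|-------------------------------------------|--------|
| 8mer    | revcomp(2–8) followed by A                | 3      |
| 7mer-m8 | revcomp(2–8)                              | 2      |
| 7mer-A1 | revcomp(2–7) followed by A                | 1.5    |
| 6mer    | revcomp(2–7)                              | 1      |

All overlapping matches are reported, but a match whose interval lies
inside a longer-class match at the same locus is suppressed (one locus,
one site). G:U wobble pairing is not allowed: the match definition stays
exact and checkable by brute-force rescan. Pairs with weighted score
≥ `min_score` (default 2: one strong site or two weak ones) become
candidates. Seed matching is a candidate generator only — its false
positive rate is high by design — and the *negative-correlation filter*
does the real work: a pair (m, g) survives iff m is a significant DE
miRNA, g passes p < 0.05 and FDR < 0.05 in the mRNA table (the same
thresholds as the miRNA gate, since no separate mRNA cutoffs are more
defensible), and sign(g's log2 FC) is opposite to sign(m's log2 FC).

## Enrichment and networks

Over-representation of a foreground of $n$ genes against a term with $K$
background members in a universe of $N$: one-sided hypergeometric tail
$P(X \ge k)$. The foreground for the "down" analysis is the pooled union
of the downregulated miRNAs' filtered (hence upregulated) target genes,
and symmetrically for "up" — pooled rather than per-miRNA, because the
network stage re-attributes genes to individual miRNAs anyway. The
background is the annotation universe (all genes carrying at least one
term), and foregrounds are intersected with it before testing. Terms with
zero overlap are excluded from the tested family; BH runs separately
within each domain (BP, MF, CC, pathway), which are reported as separate
panels/networks. GO annotations are used as given — no propagation up the
ontology graph is performed.

Networks are built per (direction, domain). Nodes: significant miRNAs of
that direction and significant terms of that domain, each with ≥ 1
positive-score edge (isolated nodes and zero-score edges are dropped —
a zero-width edge encodes nothing). Edge score =
|filtered targets of the miRNA ∩ term genes ∩ foreground|, an integer
bounded by both set sizes. Term nodes carry `fold_enrichment` and
`neg_log2_p`; either can legitimately serve as the "enrichment value"
driving node color in a rendering, so both are exported.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of a two-condition unreplicated
small-RNA study: a species-ordered mature reference whose sequences share
no 17-mer (so mapping truth is unambiguous); Truseq-style reads = mature
sequence (± 1 nt at the 3' end) + adapter, truncated to 36 nt, Phred+33,
with a degraded-read fraction exercising the quality filter and a
contaminant fraction (default 0.20) of random sequence emulating unmapped
clean reads; baseline abundance log-uniform over 50–2000 CPM, reflecting
the skewed abundance of real libraries; planted miRNAs with
treated/control expectation ratio $2^{\text{effect}}$. The default
planted design is 9 downregulated and 3 upregulated miRNAs, two of them
present only in rodent references, with |log2 effect| = 2. The fast count
path samples multinomially per library at fixed depth (the conditional
test conditions on totals, so exact totals are the right emulation);
per-feature lognormal dispersion is available but defaults to 0.

On the mRNA side, each planted target gene's UTR receives exactly one
7mer-m8 or 8mer site of its regulator at a uniform position, and its DE
record gets the opposite sign (|log2 FC| ~ U(1,3), p ~ 10^-U(3,8));
optional decoy genes get a real site but a *same*-sign significant DE
record. All other UTRs are rejection-sampled (cap: 10 000 attempts) to
contain no 6mer seed match of any planted miRNA, so a brute-force scan
can recover the planted pairing exactly. When one planted miRNA's site
string unavoidably contains another's 6mer core, the contamination check
masks the inserted windows rather than looping forever; as a result a
*hosted* UTR may rarely contain a foreign planted site inside or at the
junction of an inserted window — non-hosted UTRs are always clean.
Annotation terms are drawn from the background; planted enriched terms
stay small (size ≤ 2× overlap) so the planted overlap dominates, and
alternate deterministically between the down- and up-direction target
pools.

Not emulated: RNA secondary structure, ligation/GC bias, isomiR ladders
beyond ±1 nt, multi-isoform UTRs, genomic multi-mapping, and biological
replicate variance. Passing tests therefore demonstrate correctness of
the algorithms and calibration under counting noise — not robustness to
the full messiness of wet-lab libraries.

## Numerical conventions and degenerate inputs

- All randomness flows from one root seed; the pipeline derives per-stage
  substreams via `SeedSequence(root, spawn_key=(stage,))`, so toggling a
  stage never shifts another stage's stream. Fixed seed ⇒ byte-identical
  outputs (sha256-checksummed in the run manifest).
- Strict inequalities everywhere in significance gates.
- p-values are clamped to (0, 1]; `-log2 p` is computed from the clamped
  value.
- Zero kept reads yields an all-zero composition row flagged `degenerate`
  rather than NaNs; an empty direction yields an empty network, not an
  error; an empty enrichment input yields an empty table.
- A corrupt FASTQ record aborts the run naming the stage and the read id.

## Problem sizes used by the test suite

The suite and the acceptance script run everything at desk scale, chosen
to make each statistical check sharp but quick: DE recovery uses 300
features at depth 10⁶ per library over 20 seeds; type-I control pools
~15 000 null tests (50 seeds); the exact-test oracle enumerates all count
splits with total ≤ 200 (≤ 60 for unequal library sizes); the filter and
network checks use 600 genes, 300-nt UTRs, and 5 decoys per miRNA; the
end-to-end demo uses 50 000 reads per library, 1 200 genes and 40 terms.

## Known limitations

- The conditional binomial test treats library totals as fixed and
  captures sequencing noise only; with single libraries, biological
  effect-size estimates are optimistic and the anti-correlation and
  enrichment stages are the intended guards.
- Seed matching ignores pairing thermodynamics, 3'-supplementary pairing
  and site context; its per-class weights are a fixed convention, not a
  fitted model.
- Cross-species rescue assumes mature sequence conservation; it cannot
  distinguish a conserved ortholog from a spurious exact match, which is
  why the `min_cpm` expression floor exists.
- Enrichment treats annotation as flat sets; GO true-path propagation and
  term redundancy reduction are out of scope.
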