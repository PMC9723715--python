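# Methods

This note documents the models, rules and numerical conventions implemented
in `virotriage`, the choices made where the design was genuinely open, and
what the synthetic-data tests do and do not demonstrate about real data.

## Data model

Two compartments of the same sample set are analysed jointly: the *virome*
(VP; DNA from purified viral particles) and the *microbiome* (P; bulk
community DNA). Contigs carry a compartment tag, a length, a circularity
flag and optionally their sequence. All external-tool knowledge enters as
*evidence rows* — `(contig, source, category, subject type, E-value, gene
index)` — so that the pipeline is a deterministic function of contigs,
counts and evidence. Coordinates are 0-based half-open; minus-strand ORFs
are reported in forward-strand coordinates.

## Contig-level primitives

**Length filter.** Contigs must be *strictly* longer than 2000 nt
(default `min_len=2000`), reading "above 2 kb" literally.

**ORF caller.** Maximal ATG-to-stop open reading frames under the standard
genetic code, on both strands, minimum 150 nt (multiple of 3, stop codon
included in the span). Per frame, an ORF runs from the first ATG after the
previous stop to the next stop. The original analysis pipeline's gene caller
is not public knowledge; since ORF counts only feed the protein-profile
fraction (a ratio with the same caller in numerator and denominator), a
simple deterministic caller is preferable to an external dependency. Codons
containing non-ACGT characters never match a start or stop and the caller
warns when such characters are present. The test suite checks the caller
against an independent brute-force six-frame scanner on random sequences.

**Circularity.** A contig is circular iff its first k = 20 nt equal its
last 20 nt exactly — the terminal-direct-repeat convention assemblers
produce for circular molecules. Exact matching keeps the call deterministic;
the chance of a spurious repeat on random sequence is 4⁻²⁰.

## Triage cascade

Stages run in priority order, each seeing only still-unlabelled contigs;
permuting evidence rows never changes a label (duplicate rows resolve to
the lowest E-value, ties to lexicographically smallest category).

1. **SORTER** — any viral-sorter verdict, *all categories accepted* → PHAGE.
2. **INOVIRUS** — inovirus-detector verdict (putative or confirmed) →
   INOVIRUS. Inoviruses count as phages and as viral in every tally.
3. **HOMOLOGY_PHROG** — a nucleotide hit at E < 10⁻¹⁶ proposes the label of
   its subject (phage / eukaryotic virus / bacterial / plasmid). The
   protein-profile rule — at least 5 ORFs and an *inclusive* ≥ 35 % of them
   with a profile hit at E < 10⁻¹², fraction computed against all called
   ORFs — can (a) label a contig with no nucleotide candidate PHAGE, and
   (b) override a *bacterial* candidate to PHAGE. The override exists
   because a bacterial nucleotide hit is exactly what an integrated
   prophage looks like; plasmid and eukaryotic-virus candidates are not
   overridden.
4. **SECONDARY** — fallback classifier verdict → PHAGE or EUK_VIRUS. The
   category-string mapping (phage/prophage → PHAGE; virus → EUK_VIRUS;
   otherwise the row's subject type, defaulting to PHAGE) is a package
   default exposed in `TriageConfig.secondary_map`, since no canonical
   mapping exists.

The two-pass design splits contigs on *total* RPKM summed over samples,
strictly greater than `rpkm_cut = 100`. The low-abundance pass runs only
SECONDARY and INOVIRUS — the stages that were actually applied to
low-abundance contigs in the workflow this models.

**Percentages** are rounded half away from zero (to integers unless stated
otherwise): that convention reproduces every printed value the package
re-derives (82/18/83/13/75/14). One published figure (1.7 % for 3/168)
appears to be a truncation of 1.79 %; the package reports the computed 1.8
and does not emulate truncation.

## Abundance

`rpkm = r / ((L/1000)(M/10⁶))` with M the *total mapped reads* of the
sample (whether the original denominator was total or mapped reads is not
stated; mapped reads is the standard choice and is scale-invariant in the
tests). Sample totals may exceed per-contig sums — reads mapping to
sub-threshold contigs still count toward M.

**Dereplication** is greedy centroid clustering on a *precomputed* pairwise
table (the package does not align genomes): contigs sorted longest-first
(ties lexicographic), each joining the first representative with identity
strictly > 0.95 and aligned coverage of the shorter contig ≥ 0.80
(MIUViG-style; only the identity threshold is inherited from the modelled
workflow, the coverage criterion is a package default). The result is
order-independent in the pair list and is checked against a brute-force
restatement on all random instances of ≤ 10 contigs.

**Clade matrix** rows follow the fixed order Tubulavirales, Petitvirales,
non-bacterial viruses, Caudovirales, Bacteria, Plasmids, Unclassified;
per-clade shares of total RPKM sum to 100 within 10⁻⁹. ssDNA and dsDNA
abundances are not comparable after multiple displacement amplification;
this is a reporting caveat, not a correction — no amplification-bias model
is implemented. Group comparisons use Welch's two-sample *t*-test
(`scipy.stats.ttest_ind(equal_var=False)`); identical zero-variance groups
report p = 1.

## Activity

Viral-P identification is the **union** of three criteria (any one
suffices): fallback-classifier positive, homology to a viral virome contig,
viral taxonomic affiliation. Removing a criterion can only shrink the set.

The activity partition operationalises "covered by a significant amount of
virome reads" — whose original quantitative threshold is not publicly
stated — as breadth ≥ 0.50 **and** total virome RPKM ≥ 1.0, both
configurable and documented here as package decisions. When per-base depth
profiles are absent, breadth is estimated as `min(1, reads · read_len / L)`
with `read_len = 150`. Raising a contig's virome reads can only move it
dormant → active.

The overlap report merges both compartments' viral contigs into connected
components under the same > 95 % / ≥ 80 % homology rule (for internal
consistency with dereplication) and partitions components into shared /
virome-only / microbiome-only (active if any member is active). Virome RPKM
shares are reported over the three read-covered subsets. Because the
published survey prints a dormant percentage under a slightly different
denominator than the viral-P total, the reference report states the
denominator it uses explicitly rather than guessing.

## ARG census

Tiers: SENSITIVE (profile search), HOMOLOGY (protein homology), CONFIRMED
(stringent search against experimentally confirmed genes). Tiers union per
(contig, gene); CONFIRMED is independent — a confirmed gene can be missed
by both broader searches. Generic transporter families (ABC/RND/MFS efflux)
appear only in the sensitive tier of real tools, are likely false positives,
and are flagged `low_confidence`; `confirmed_hits()` excludes them, so
headline rates rest on the stringent tier.

Rates: ARG per gene (`n/n_genes`), ARG per Mb (`n/assembled_mb`), per
3-Mb bacterial genome, and per phage genome at 30 ORFs per 30-kb genome —
one gene per kb, the only reading consistent with a per-ORF bound of
1.2·10⁻⁵ implying 3.6·10⁻⁴ per genome. Zero-ARG compartments report upper
bounds with a pseudo-count of one (1/denominator); the enrichment ratio
(bacterial per-genome rate over phage per-genome bound) is then a floor.
Detection limits are monotone: more assembled sequence tightens them.

## Synthetic communities

The generator emulates the *structure* of the paired design, not sequence
evolution: random codon-cassette DNA (ATG + 50–100 sense codons + stop), so
every contig yields ≥ 5 called ORFs; exact 20-nt terminal repeats on
planted circular contigs; near-duplicates at 98 % identity for
dereplication; cross-compartment homologs at 97 %; ARGs placed on named
genes at per-Mb Poisson rates (transporter decoys at a quarter of the
confirmed rate); evidence rows consistent with the planted truth, corrupted
at configurable per-row false-negative/false-positive rates.

Defaults mirror the modelled study's conditions: 14 samples, 7.7 % of
microbiome contigs viral, 23.7 % of those active, 0.18 confirmed ARGs per
bacterial Mb, none on phages, contig lengths 2.5–30 kb.

Read simulation allocates a multinomial per sample with an explicit
unmapped-read sink, so each contig's expected total RPKM equals its planted
target regardless of depth or sample count. Planted abundances are bimodal
(high band 250–1200 total RPKM, low band 2–50) so the 100-RPKM pass split
survives sampling noise at the default depths. Virome bacterial/plasmid
contigs draw reads from a contamination budget capped at
`contamination_fraction` of the virome and floored at total RPKM 300 —
they are assembled *from* virome reads, so they are well covered by
construction; specs whose budget cannot support that floor are rejected as
infeasible, and with zero contamination these contigs (and all dormant
prophages, which otherwise receive only a small cross-mapping spillover far
below the activity floor) receive no virome reads at all. Active prophages
are planted at high virome abundance, consistent with virions dominating
virome DNA. Low-abundance virome contigs only ever carry evidence the
low-abundance pass consults (fallback classifier, inovirus detector),
mirroring the modelled two-pass workflow.

What passing tests show: the decision logic — cascade order, thresholds,
union rules, activity partition, tier merging, detection-limit arithmetic —
is exactly right on inputs whose truth is known, across seeds. What they do
not show: robustness to assembly fragmentation, chimeras, real sorter error
profiles, amplification bias, or uneven coverage; those live in the
upstream tools whose outputs this package consumes.

## Problem sizes and numerics

The default test suite runs communities of up to 500 contigs × 4 samples at
1.5·10⁵ reads per sample, 200 random dereplication instances, and one 60-Mb
metadata-only community for ARG-rate convergence (the generator can skip
sequence construction, `with_sequences=False`). The rate-convergence check
plants 2 ARGs/Mb — about 120 expected events at 60 Mb, where Poisson shot
noise (~9 %) sits comfortably inside the 20 % acceptance band; at the
study-scale 0.18/Mb a 50-Mb community would contain ~9 events and any such
check would measure shot noise, not the estimator. All randomness flows
from a single integer seed through independent, purpose-keyed NumPy
generator streams (generation / counts / evidence), so artefacts are
byte-identical across reruns and invariant to which outputs are requested.

## Known limitations

* Pairwise identities and cross-compartment homology are inputs; the
  package never aligns sequences, so dereplication quality is bounded by
  the supplied table.
* Breadth from read counts is an upper-bound estimate (assumes no read
  stacking); supply `depth_profiles` for exact breadth.
* The activity thresholds (0.5 breadth, RPKM 1) are package defaults, not
  values inherited from the modelled workflow, and should be calibrated
  when per-base coverage is available.
* Prophage boundaries within bacterial contigs are not called; a "viral"
  microbiome contig is treated as viral end to end.
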