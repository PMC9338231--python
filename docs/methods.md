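# Methods

This note documents the models, parameters and design choices behind
`flymplex`, what the synthetic data does and does not emulate, and the
known limitations.

## Primer binding and amplicon prediction

A primer is considered annealed at a template position when, comparing
base by base with IUPAC set-intersection matching, the number of
mismatches does not exceed `max_total` over the whole primer and
`max_3prime` within the `three_prime_window` bases at the primer's 3'
terminus. The default policy is **(2, 5, 0)**: up to two mismatches
anywhere, none in the terminal five bases. This encodes the standard PCR
heuristic that 3'-terminal mismatches abolish polymerase extension — the
mechanism that makes species-specific priming work, and the reason the
assay tolerates internal intraspecific variation without false negatives
while a single 3'-terminal variant kills the product. No annealing
thermodynamics or amplification kinetics are modeled; binding is a
yes/no decision under the policy, and primer concentrations are carried
as assay metadata only.

Amplicons pair *every* plus-strand site with *every* downstream
minus-strand site across all primers of the panel, not just same-species
pairs; this is what lets the engine predict the observed cross-species
duplex artifact. Product length includes both primer footprints
(`rev.end − fwd.start` in 0-based half-open plus-strand coordinates).
Overlapping footprints produce nothing. The default length cap is
**3000 bp**, a generous bound on what a 35 s extension step can produce;
it also keeps pathological distant pairings off long contigs.

Site search is vectorized (numpy, per-position mismatch accumulation over
a 15×15 IUPAC match matrix); the test suite holds it to exact agreement
with a brute-force two-strand sliding-window scan on hundreds of random
instances.

## Melting temperature and multiplex-compatibility screens

Tm uses the unified DNA/DNA nearest-neighbor parameters (SantaLucia
1998), shipped as a plain-text table so an alternative set can be swapped
in. Conditions are pinned at 50 mM monovalent salt (entropic correction
`ΔS' = ΔS + 0.368 (N−1) ln[Na+]`) and 250 nM total oligo
(`Tm = 1000·ΔH / (ΔS' + R ln(CT/4)) − 273.15`, with the symmetry term and
`CT/1` for self-complementary sequences). Degenerate bases are rejected by
default; an expansion mode averages over explicit expansions capped at 64.
Under this model the ten published primers compute to 47.9–51.9 °C.
Absolute Tm under the actual PCR buffer (which contains Mg²⁺) would be
several degrees higher; only self-consistency matters here, since the
package uses Tm solely as a design filter.

Dimer and hairpin screening are alignment-run based, not thermodynamic:
the dimer score is the longest contiguous Watson–Crick complementary run
between two primers annealed antiparallel, counted only when the run
touches either primer's 3'-terminal window (default 5); the hairpin score
is the longest self-complementary stem closable with a loop of ≥ 3 nt.
This matches the screening level of interactive design tools of the
assay's era; duplex ΔG models are deliberately out of scope.

## Virtual gel

Migration is affine in log₁₀(size), normalized so the 100 bp ladder
extremes map to 1 (smallest, farthest) and 0 (largest). Two sizes are
resolvable when they differ by ≥ `resolvability_delta` in log₁₀ units;
unresolvable amplicons in a lane merge into one band whose support counts
the merged products. The default delta **0.04** (≈ ±4–5 % in size) is
calibrated against the one resolution fact the assay record establishes:
128 vs 183 bp separate cleanly on 2 % agarose (Δlog₁₀ ≈ 0.155), with a
wide margin, while sizes a few percent apart do not. The true minimum
separable Δbp of any particular gel rig is unknown; the constant is
configurable on `GelModel`.

## Species calling

A band matches a species when it is within a relative `size_tolerance`
(default **8 %**) of that species' declared size. Eight percent is wide
enough for gel-estimated sizes (±~10 bp near 150 bp) and narrow enough
that adjacent declared sizes of the builtin panel can never co-match one
band; `validate_tolerance` enforces window disjointness for any
panel/tolerance combination before calling.

The duplex rule: the *C. quilicii* pair lies in an intergenic region and
can cross-amplify in related species, so a band at the quilicii size
co-occurring with any *larger* band matching a different species is
discounted (recorded in `discounted_bands`), and quilicii is called only
when its size is the sole diagnostic match. The rule is driven by the
`cross_amplification_risk` flag on the panel entry, not by a species
name, so designed panels can use it too. Decision order: empty lane →
`no_amplification`; one surviving diagnostic species → `identified`
(extra non-diagnostic bands never block the call); two or more →
`ambiguous` (reported, not resolved — a single-insect assay should never
reach this branch, so it is a conservative extrapolation); bands but no
diagnostic match → `unrecognized_bands`. A band in a no-template-control
lane flags the whole run as contamination-suspected.

## Panel design

Per-species consensus is majority rule with IUPAC ambiguity on ties (a
necessity with two sequences per species); a column is *diagnostic* for
the target when its consensus base is unambiguous and its base set is
disjoint from every other species' consensus base set. Windows of primer
scale (25 columns, sliding by 1) qualify when they hold at least
`min_diag_positions` (default 2) diagnostic columns with one in the
3'-proximal third for the orientation in question; they are ranked by
diagnostic count, then 3' proximity. The best windows are taken per
orientation so both primer directions get candidates even when one SNP
cluster dominates the ranking.

Candidates are degapped consensus subsequences (18–25 nt) whose
3'-terminal five bases cover a diagnostic column — species-specificity is
enforced at the 3' end, consistent with the binding policy; internal-only
discrimination is rejected. Filters: Tm 46–60 °C, GC 0.30–0.70, hairpin
stem ≤ 5, homopolymer ≤ 5, within-pair dimer run ≤ 6. These defaults are
reverse-engineered from the measured properties of the ten published
primers under the pinned Tm model (length 18–22, Tm 47.9–51.9 °C, GC
0.32–0.50, hairpin ≤ 5, worst intra-panel dimer run exactly 6), so the
published panel is a fixed point of its own validator; all remain
configurable on `DesignConstraints`.

Specificity: a pair is at risk for a non-target when both primers bind
its degapped consensus under the looser policy **(3, 5, 1)** in a
productive orientation with a product inside the amplicon range
(100–700 bp). At-risk pairs are dropped, or retained with a recorded
warning in `warn_only_specificity` mode — representing the compromise the
published panel knowingly made with its intergenic quilicii pair.

Size assignment selects one pair per species maximizing the minimum
pairwise log₁₀ size gap, subject to all pairs being gel-resolvable:
exhaustive search up to 10⁵ combinations, otherwise a deterministic beam
search (width 64) over species ordered by ascending candidate count, with
lexicographic tie-breaks. Infeasibility names the blocking species pair.
A final cross-panel dimer check drops offenders and re-selects (bounded
retries). Identical inputs give byte-identical results; there is no
randomness anywhere in the design path.

Gene selection upstream of the alignment (contig assembly, database
search) is out of scope; the pipeline starts from a provided alignment.

## Synthetic data

`synth_template` builds flank + forward primer + spacer +
revcomp(reverse primer) + flank with the primer-to-primer span exactly
the declared size (default flanks 150 bp, GC 0.5), rejection-resampling
the filler (budget 1000 attempts) until no panel primer has any
unintended binding site under the default policy — verified in tests by
the brute-force scan. `synth_duplex_template` adds a second,
cross-amplifying cassette 3000 bp downstream, so the outer
forward×reverse pairing of the two cassettes exceeds the amplicon cap and
exactly the two intended products remain — the geometry implied by a
cross-amplifying intergenic locus far from the diagnostic one.
`inject_mutations` substitutes template bases at a primer footprint,
addressed by offset from the primer's 3' end as annealed, picking a
mismatching base deterministically when none is specified; it
demonstrates the false-negative mode (3'-terminal variant) and its
absence (internal variant).

`synth_alignment` derives five species from one random ancestral sequence
(800 columns, GC 0.5, homopolymer runs capped at 4 — a locus *chosen for
primer design* is by selection primer-placeable, so the generator bounds
the runs that would otherwise randomly forbid candidate windows). Each
species receives `diag_per_species` private SNPs (deterministic
transversions) clustered in the 3'-proximal five columns of a forward
window and the 5'-edge five columns of a reverse window, the windows
spaced to that species' target amplicon size (140/200/280/400/560 bp —
pairwise log-gaps well above the gel delta); per-row noise at 0.2 %
emulates within-species polymorphism, never touching implanted columns.
The manifest records every implant so recovery tests can assert that
designed primers sit on the implanted diagnostics.

What the fixtures do **not** emulate: real intergenic composition and
codon structure, indels and alignment error, heterozygosity, population
structure within species, or sequencing error. Passing the recovery tests
therefore shows the pipeline recovers clean, well-posed signal — not that
it would succeed on arbitrary field data.

Problem sizes used by the test suite and acceptance script: templates of
~0.4–4 kb, alignments of 800 columns × 10 rows, a 75-template validation
cohort (15 seeded templates per species, the in-silico analogue of a
15-specimens-per-species validation), and ~200-instance oracle
equivalence sweeps. The whole suite runs in well under a minute on one
core.

## Numerical and degenerate-input choices

Coordinates are 0-based half-open on the plus strand throughout, with
strand recorded separately. U→T and lowercase are normalized on input;
gaps are rejected in templates but allowed in alignments. A primer longer
than its template yields an empty site list, not an error. Equal-size
bands merge by single linkage in descending size order, band size being
the rounded mean of the merged products. `min_diag_positions=0`
degenerately returns every window. Ties everywhere break
lexicographically so serialized outputs are byte-stable.

## Limitations

* No quantitative PCR model: detection limits, band intensity and
  competition between pairs in a multiplex are outside the scope; a
  predicted product says a product is *possible*, not how bright it is.
* Tm values are model- and condition-relative; they are filters, not
  predictions of buffer-specific melting behavior.
* The caller is only as good as the panel's size spacing and the
  configured tolerance; `validate_tolerance` guards the published panel
  but custom panels with close sizes need a tighter tolerance.
* Specificity screening is limited to the species present in the input
  alignment; behavior on untested related species is unknown, exactly as
  for the wet-lab assay.
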