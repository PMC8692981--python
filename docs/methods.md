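# Methods

## The model

A multipartite mitochondrial genome is modeled as a set of **circular
molecules** over a common pool of sequence units: single-copy scaffolds,
each used exactly once, and repeat units (>1 kb, near-identical), each
present in exactly two copies. A **conformation** is one such set of
circles; two conformations are *equivalent* when their circles agree up to
rotation and strand (we canonicalize each circle to the lexicographically
smallest signed unit sequence over all rotations of both strand readings,
and a conformation to the sorted tuple of circle canonicals).

Three recombination events connect conformations:

* **fusion** — a direct repeat with one copy on each of two circles
  `[r, A…]` and `[r, B…]` yields the single circle `[r, A…, r, B…]`;
* **fission** — the exact inverse, splitting a circle that carries both
  same-orientation copies;
* **inversion (flip-flop)** — an inverted pair on one circle
  reverse-complements the arc strictly between the two copies. Working the
  signed algebra through shows this swaps the repeat copies' successor
  units (contexts `A-r-D` / `K-r-F` become `A-r-F` / `K-r-D`) while leaving
  circle count, length, and base composition unchanged; the two possible
  arcs give the same circle up to rotation/reverse-complement, so the
  operation is well defined.

The **conformation space** is the breadth-first closure of a base state
under all currently valid events. Independent repeats multiply: three
direct repeats and one inverted pair give a 2⁴-state space whose extreme
states are the all-split (five-circle) and all-fused (two-ring) forms.
Total length is conserved exactly across the space — an invariant the
tests assert as integer equality.

## Evidence model

**Junctions.** A 500 bp terminal anchor per scaffold end; a long read that
exits one scaffold (through its tail when mapped forward, head when
reverse) and enters another within `max_gap=500` bp contributes one
observation. Edges need `min_support=2` distinct read ids. Anchor mapping
requires ≥80% identity over ≥50% of the anchor; the junction position on
the read is extrapolated from the anchor's unaligned remainder so gap
estimates stay accurate when alignments are trimmed at 10% read error.

**A structural subtlety that drives the design:** the fused and split
states of a direct repeat realize *identical* junction edge sets
(`[r,A…,r,B…]` and `[r,A…]+[r,B…]` produce the same unordered end pairs).
They differ only in how entry edges pair with exit edges *through* the
repeat. Consequently:

* `decompose_circles` enumerates decompositions by backtracking over
  scaffold-end *usage capacities* (copy number per end) rather than edge
  subsets, which explores all through-pairings and therefore recovers both
  fused and split states from one graph;
* `estimate_mixture` counts, per repeat, reads whose ids appear on both an
  entry and an exit edge — i.e. reads long enough to span the whole repeat
  plus flanking anchors. Per diagnostic site the state's share is its
  supporting-read fraction; overall frequencies are the unweighted mean
  over sites (a plain counting estimator, no latent-variable machinery —
  with a caveat inherited from the underlying counting argument that
  junction-spanning samples are small). Junction edges that differ between
  states (possible for inverted pairs in asymmetric contexts) are used the
  same way when present.

**Depth.** Short reads are assigned to scaffolds by exact 21-mer matches
(canonical-strand keys); a k-mer matching *n* index positions adds 1/*n* at
each, preserving the 2× pile-up on collapsed repeats instead of discarding
multi-mappers. Counts are rescaled by L/(L−k+1) so per-position depth
tracks read coverage. The single-copy baseline is the median of
per-scaffold medians after excluding scaffolds at ≥1.5× a provisional
all-scaffold baseline; copy number is the half-up-rounded ratio (floor 1),
and a scaffold is flagged repeat at copy ≥2 (the spec-level alternative
route — ratio ≥1.5 with two distinct neighbor contexts on one end — is
implemented but is subsumed by half-up rounding).

**Local alignment.** One aligner serves contig classification, anchor
mapping, repeat discovery, and MTPT detection: exact k-mer seeds (default
k=13; k=21 for ≥98%-identity repeat search) indexed on both strands, seeds
clustered within ±30 diagonals, the chained core aligned end-to-end with
edlib (anchored at exact seed matches on both ends), and each flank grown
by semi-global extensions trimmed to their maximum-scoring prefix,
iterated so the alignment can push through local error bursts (x-drop at
window scale). Scoring is match +1 / mismatch −1 / gap −2; identity is
matches over alignment columns. Against a full quadratic Smith-Waterman
oracle the reported identity agrees within one point on mutated pairs up
to ~12% divergence (asserted over 100 seeded trials).

**MTPT.** Local alignments of mitochondrial molecules against the plastid
genome at ≥70% identity (below the ~74% floor of real organelle transfers,
so the oldest detectable class is retained) over ≥200 bp; overlapping
mitochondrial intervals merge to their union keeping the best-identity
donor interval. Coverage fractions are interval unions in the chosen
coordinate space — mitochondrial and plastid-side fractions legitimately
differ when several insertions trace back to overlapping donor regions.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, with
defaults at the study scale: ~200 kb across ten single-copy units of
8–30 kb, four repeats (direct 5,212/3,908/4,926 bp, inverted 2,351 bp),
background composition i.i.d. at 44.7% GC, long reads log-normal
(dispersion 0.4) with mixed errors at a PacBio-CLR-like
substitution:insertion:deletion ratio of 0.25:0.45:0.30 (declared defaults;
no platform-specific profile is fitted), and paired
short reads at ≥50× with substitution errors only. The default layout
mirrors the resolved architecture: a hub circle carrying one copy of each
bridging direct repeat plus both inverted copies, satellites carrying the
second copies, and a separate two-circle component — so recombination can
fuse each component into a master ring but never join the components.
Circular reads use the doubled-sequence trick (concatenate, sample starts
in the first copy). Coordinates are 0-based half-open throughout;
qualities are constant placeholders (nothing downstream uses them).

Plastid insertions copy a random donor interval, apply substitutions only
(no indels), and splice into a random single-copy scaffold at a site
avoiding earlier insertions; truth records both coordinate systems and the
realized identity, which keeps the ±1-point identity-recovery check
well-defined.

What the generator does **not** emulate — chimeric/adapter artifacts,
quality-dependent error models, heteroplasmy beyond the conformation
mixture, diverged repeat copies, nuclear contamination — bounds what
passing tests show: they validate the graph/algebra/estimation machinery
under the assumed architecture, not robustness to every artifact of real
libraries.

## Problem sizes and numerical choices

The end-to-end recovery runs use a ~90 kb five-circle genome (eight
single-copy units of 7–9.5 kb, four 2 kb repeats) with 1,000 long reads at
8 kb mean / 10% error and 50× short reads. The size was chosen from read-
budget arithmetic: a diagnostic read must span a full repeat plus flanking
anchors (~2.5 kb), and at this scale the expected count of such reads is
≈350–400, enough for the mixture estimate's ±0.05 binomial check. With
~390 diagnostic observations one standard error is ≈0.025, so individual
seeds can land near the band edge; the packaged runs use fixed seeds.

Rounding follows print conventions: percentages half-up (2 decimals for
composition, 1 for genome fractions); scaffold median is the mean of the
two central values for even counts. Ties in contig classification go to
the mitochondrial label (the pipeline's focus) with both hits recorded.
Decomposition enumerates circles starting at the smallest-id available
scaffold with results deduplicated by canonical form; repeat copies are
unlabeled, so copy-swapped decompositions coincide by construction.
Degenerate inputs are errors, not silent defaults: empty scaffold sets,
anchors under 50 bp, k outside [4, 31], missing depth entries (named
scaffold), inserts shorter than twice the read length, fragments at ≥100%
divergence or exceeding the donor.

## Known limitations

* `decompose_circles` is exhaustive backtracking — exact and fast to ~24
  scaffolds, not meant for hundreds.
* The mixture estimator averages per-site proportions; sites with few
  spanning reads get equal weight, and states indistinguishable by any
  junction or through-pairing (none in the architectures here) would be
  inseparable.
* Repeat discovery assumes near-identity (≥98% by default) between copies,
  consistent with repeats that actively recombine; older, diverged repeat
  pairs need a lower threshold and will blur the direct/inverted
  classification at the margins.
* Plastid-side coverage of real MTPT sets can exceed what the printed
  fragment lengths suggest when donors overlap inverted-repeat copies of
  the plastid genome; the package reports the plain union in each
  coordinate space and leaves such reconciliation to the caller.
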