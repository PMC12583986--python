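# Methods

## Scope and model

`bhpdkit` links bacterial genotype to hopanoid chemotype. Hopanoids are
pentacyclic triterpenoid membrane lipids; the C35 members
(bacteriohopanepolyol derivatives, BHPDs) carry a polyfunctionalized side
chain and are widely used biomarkers. The package implements four layers:

1. **Gene detection.** Each gene family of the pathway (MEP isoprenoid
   supply `dxs…ispH, ispA`; squalene synthesis `hpnC/D/E`; squalene-hopene
   cyclase `shc`; side-chain genes `hpnG, hpnH, hpnI/J/K, hpnO`; ring-A
   methyltransferases `hpnP, hpnR`; transport/accessory
   `hpnN, hpnM, hpnA/B/L`; tetrahymanol synthase `ths`; two
   desaturase-like families) is searched by optimal local alignment of a
   reference query protein against every protein of the genome, scored
   with BLOSUM62 and affine gaps (open 11, extend 1; a gap of length *n*
   costs `11 + (n−1)`). A candidate is accepted when its **percent
   similarity** — positive-scoring aligned columns over all alignment
   columns, the BLAST "positives" convention — reaches the family
   threshold and the alignment covers ≥ 70 % of the query. Thresholds
   default to 50 % similarity; `hpnP` uses 55 % because other
   B12-binding radical-SAM proteins reach the high 40s. Proteins annotated
   as Shc but < 40 % similar to the reference form a distinct secondary
   clade outside the biosynthetic cluster and are excluded
   (`exclude_secondary_shc`).

   The original survey used iterative profile searches (PSI-BLAST); this
   package deliberately uses single-pass pairwise alignment. Downstream
   logic consumes only percent similarity and presence calls, but absolute
   similarities of remote homologs will differ from profile-based values —
   a known fidelity limit. A shared-4-mer seeding screen (BLAST-style)
   skips hopeless query/target pairs; `ThresholdPolicy(prefilter_k=0)`
   restores exhaustive alignment.

2. **Cluster architecture.** Accepted hits chain into a cluster when they
   share a contig and are separated by ≤ G intervening non-pathway genes
   (default 5) *or* their locus-tag numbers differ by ≤ L units (default
   50; annotation pipelines step locus tags by 5 per gene). Both
   tolerances are explicit because real clusters tolerate small unrelated
   insertions. Gene order is scored against the canonical
   `hpnA…hpnN` order (with `shc` in the F slot) by Kendall tau-a computed
   with exact integer pair counts over the genes present; each fragment is
   strand-normalized by the majority rule so a minus-strand operon scores
   like its mirror, and fragments are concatenated by earliest canonical
   rank. `hpnO`, `hpnP`, `hpnR`, `ths` and the desaturases are excluded
   from order scoring — they typically sit outside the cluster.

3. **Chemotype rules.** `shc` permits C30 hopanoids; `+hpnH`
   adenosylhopane and hence any BHPD; `+hpnG` BHT; `+hpnO` the
   35-aminotriol; `hpnI/K/J` select the terminal cyclitol-ether stage
   (acetylglucosamine → glucosamine → cyclitol ether); `hpnP`/`hpnR`
   confer ring-A methylation *capacity* at C-2/C-3; `ths` tetrahymanol.
   All flags are capacities, not guarantees — the species panel itself
   contains gene-positive, product-negative cases for both
   methyltransferases, and the concordance layer treats that as a distinct
   outcome, never an error. BHpentol, BHhexol and unsaturation have no
   established genes, so no flag asserts them; a desaturase-like gene only
   raises an advisory `unsaturation_suggested`. "Unknown" gene states
   (possible only in fixture-derived genotypes) never switch a flag on;
   they surface as confidence notes. The cumulative flags are monotone
   under gene addition; the three CE-stage flags are deliberately
   exclusive (adding `hpnK` *advances* the stage), so the monotone
   guarantee applies to the accumulating flags plus the union of the CE
   stages.

4. **Measurement arithmetic and degradation.** Concentrations are
   semi-quantitative against the n-tricosan-1-ol internal standard
   (response factor 1): `(analyte/IS area) × IS mass / biomass`, with
   0.03075 mg the default IS mass (150 µL of 0.205 mg/mL). Degree of
   ring-A methylation is `100·Me/(Me+non-Me)` over separate MRM channels —
   non-methylated skeletons on the transition to *m/z* 191, methylated on
   *m/z* 205 — so coelution cannot bias the ratio; both-zero input is an
   error, not 0. The 22S epimer fraction is `100·S/(S+R)`. Both ratios are
   scale-invariant. Relative-abundance inventories are normalized to 100 %
   with zero-response structures dropped; values under the 0.01 %
   detection floor render as below-detection.

   In-silico Rohmer degradation maps each structure to its
   periodate/borohydride product: side chains without a free vicinal diol
   (nucleosides, anhydro-pentol) give none; tetrol-based chains — including
   cyclitol-ether stages, carbamoyl tetrol, the aminotriol and the
   methyl-ether/ethenolamine/acyl derivatives — give bishomohopan-32-ol;
   pentol-based chains (including the aminotetrol, whose first hydroxyl
   sits at C-31) give homohopan-31-ol; hexol-based chains give
   hopan-30-ol. Ring-A methylation, unsaturation and the C-22
   configuration carry through, which is what makes the predicted GC
   profile a cross-platform check on the LC inventory (default agreement
   tolerance 15 percentage points, configurable).

## Packaged reference data

The catalog ships **surrogate query proteins**: fixed pseudo-random
sequences (~110–400 aa, realistic residue frequencies) generated once and
frozen in the repository. They exercise every alignment/threshold code
path; no fixture-derived statistic depends on their residues, and users
analyzing real genomes should substitute curated queries.

Fixture tables transcribe the published cultivated-species panel: the
54-strain roster, the gene-survey counts over > 6500 reference genomes,
the degradation-product concentration panel (54 rows, 2 not determined),
the 18-row methylation panel, the narrated per-species genotypes
(three-valued: present/absent/unknown — genes the text does not enumerate
per species stay unknown rather than being guessed from figure artwork),
and the narrated single-structure inventories. `BD` (below detection) and
`NA` (not determined/applicable) are distinct states and never coerce to
zero; every derived count states its denominator (e.g. 52 of the 54
species were measured by degradation). A roster of 63 distinct BHPD
structures (five side-chain groups × cores × unsaturation × C-22
configuration) validates the structure taxonomy; its exact composition
beyond the named variants is a construction aid, not data.

## Synthetic data

`simulate_genome` plants mutated copies of the catalog queries in a
background of shuffled-residue genes (default 300, two contigs — enough to
exercise clustering, not genome realism), lays the cluster out in
canonical order with locus tags stepping by 5, optionally fragments it,
and can plant decoys below threshold. `mutate_protein` reaches a target
percent similarity by substituting non-positive-scoring residues and
bisecting the substituted fraction against the package's own aligner
(realized within ±5 points for ≥150-aa references). `simulate_lipidome`
draws structures only from classes the chemotype permits, abundances from
a symmetric Dirichlet, and peak areas under multiplicative lognormal noise
(default CV 0.05, the standard model for chromatographic areas; CV 0 is
exactly noiseless). Seeds are explicit everywhere; identical seeds give
identical outputs.

What the simulations do **not** emulate: real paralog structure and domain
shuffling, profile-vs-pairwise search differences, genome incompleteness,
growth-condition dependence of methylation, and response-factor
differences between analytes. Passing recovery tests therefore
demonstrates internal consistency of the pipeline, not field performance
on real genomes.

## Numerical choices and degenerate inputs

Alignment scores are integers; ties for a family's best hit break to the
lexicographically lowest protein id, and hit lists sort by (family,
protein). Empty proteomes scan to empty hit lists; an empty hit list
assembles to an all-absent genotype; architecture with no accepted core
hits is "absent" with concordance 1.0 (vacuous). Report rendering rounds
values ≥ 10 to integers and keeps one decimal below 10 (the convention of
the printed tables); raw values stay unrounded internally.

## Problem sizes

Property suites use: exhaustive oracle comparison on all 4-letter peptides
to length 3 plus 1500 sampled pairs to length 12; 200 random cluster
layouts; 1000 random genotypes; 50 end-to-end genome scenarios with
40-gene backgrounds and planted similarities 68–95 % (at least 10 points
above threshold, where exact recovery is the designed guarantee). The
acceptance script runs 20 scenarios. These sizes were chosen once as
adequate to the properties being checked.

## Known limitations

Single-pass alignment underestimates remote homology relative to
iterative profile search; similarity thresholds beyond the two stated ones
(55 % for hpnP, the 40 % Shc floor) are package defaults, not measured
cutoffs; response factors are unity; the genotype fixture leaves
non-narrated genes unknown, so fixture-level concordance is computed only
over features with named marker genes.
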