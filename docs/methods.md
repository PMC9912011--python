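# Methods

`mediagap` studies a reconstruction artefact: when a draft genome-scale
metabolic model (GEM) is completed by automated gap filling, the medium
assumed during gap filling decides *how* missing amino-acid supply routes
are repaired, and therefore which auxotrophies the finished model
predicts. This note documents the model, its parameters, what the
synthetic data generator does and does not emulate, and the numerical
choices.

## The model

**Networks and FBA.** A network is a set of bounded reactions over
cytosolic (`_c`) and extracellular (`_e`) metabolites with one biomass
pseudo-reaction. Growth is assessed by flux balance analysis: maximize
biomass flux `v_b` subject to `S v = 0` and `lb <= v <= ub`. A medium
enters only through exchange lower bounds (`lb_EX = -max_uptake`);
secretion stays open at the default bound of 1000 mmol/gDW/h. A model
"grows" when the biomass optimum reaches `epsilon = 1e-3` 1/h — strictly
positive with ample headroom above solver tolerance (1e-9), since real
platforms' thresholds are not published.

**Parsimonious gap filling.** Given a draft that cannot grow on the
reconstruction medium and a universal database U, we solve

```
min  sum_j w_j y_j                    over candidates j in U \ draft
s.t. S v = 0,   lb_j y_j <= v_j <= ub_j y_j  (candidates),
     v_biomass >= epsilon,  exchange bounds from the medium
```

with `y_j` binary and default weights `w_j = 1` (minimum reaction
count). Uniform weights are a declared stand-in: commercial platforms do
not disclose their penalty schemes, but any cost that grows with the
number of additions reproduces the decisive preference — importing a
compound (1 transporter) is cheaper than synthesizing it (a k-step
pathway) whenever the medium supplies it. Per-reaction weights are
exposed for sensitivity analysis. Equal-cost optima are accepted as
returned by the (deterministic, single-threaded) solver; analyses
compare costs and transport/biosynthesis classifications, never exact
reaction sets, because ties are genuinely degenerate.

**Auxotrophy calls.** Primary mode, `precursor_check`: amino acid `a`
is auxotrophic under medium M iff its maximal production flux (via a
temporary sink on `a_c`) is below `tol = 1e-6`. The amino acid's own
exchange keeps its medium value during the check, so uptake can satisfy
the precursor — auxotrophy is a property of the (model, medium) pair,
which is the phenomenon under study. `tol` is kept two orders below the
growth `epsilon` because producibility is a feasibility question, not a
growth-rate question. Secondary mode, `omission`: the model must grow on
the full medium and an amino acid is called iff deleting its uptake
abolishes growth; on amino-acid-free media the modes coincide.

## The synthetic world

Real inputs (annotated isolate genomes, metagenome-assembled genomes,
a curated reaction database, commercial media formulations) are replaced
by a generator with the same causal structure:

* **Universal database.** Mineral base (NH4, Pi, SO4, H2O) with
  exchanges and transporters; two lumped carbon routes
  (glucose -> 2 precursor + 10 ATP, citrate -> 1 precursor + 6 ATP),
  each a transporter plus one catabolic reaction — route existence and
  relative cost, not pathway detail, carry the results; per amino acid a
  linear biosynthesis pathway of `k = 3` genome-encoded steps
  (precursor + NH4 + ATP -> ... -> amino acid; cysteine and methionine
  additionally assimilate sulfate) *and* a transporter/exchange pair;
  a biomass reaction consuming all amino acids, 20 ATP and phosphate;
  40 decoy importers of metabolically disconnected compounds; and two
  boundary sinks, `DM_atp` (maintenance/ATP dissipation, the ATPM of
  every real GEM) and `DM_prec` (precursor overflow). Without those
  sinks steady state would forbid growth whenever catabolism
  overproduces energy — a stoichiometric artefact, not a phenotype.
  `k >= 2` is enforced: it is the engine of the mechanism (transporter
  strictly cheaper than pathway).
* **Template organism:** every non-decoy genome-encoded reaction
  (`20(k+1) + 8 = 88` reactions at defaults); prototrophic on all four
  bundled media by construction.
* **Media suite.** `citrate_min` / `glucose_min`: mineral base (uptake
  1000) plus one carbon source (uptake 10). `rich_defined`: base + both
  carbon sources + all 20 amino acids (uptake 10). `rich_complex`:
  rich_defined + the decoy-pool nutrients. Both rich media are
  compound-wise supersets of both minimal media. Including *both* carbon
  sources in `rich_defined` is a deliberate design choice: the
  formulations of the real defined/complex rich media are not public,
  and a "rich" medium that starved a citrate-reconstructed model of
  carbon would manufacture auxotrophies out of energy limitation rather
  than the gap-filling mechanism — the zeros of the headline grid are
  meant to be structural, as they are in the original experiment.
* **Degraded genomes (MAG analogue).** Each genome-encoded template
  reaction is retained independently with probability = completeness;
  contamination adds `round(contamination * 88)` decoy reactions.
  Completeness acts at the reaction level because the mechanism concerns
  missing reactions; marker-gene completeness estimation is out of
  scope. Cohort defaults — n = 106, completeness ~ U(0.60, 1.00),
  contamination ~ U(0, 0.055) — are the published ranges of the cohort
  being emulated; uniform distributions are assumed because only ranges
  are reported. Contaminants are inert by default (contamination showed
  no discernible influence in the source cohort); active contaminants
  can be simulated by adding non-decoy reactions explicitly.

**What a green test does not establish.** The generator produces no
sequences, no annotation noise, no pathway-level correlation in dropout
(real bins lose contiguous genome fragments, not i.i.d. reactions), and
its lumped catabolism makes "carbon route broken" far more likely per
lost reaction than in a 2000-reaction GEM. Quantities that depend on
those realities — the non-zero cell means, the absolute gap-filled
fractions — are qualitative here; only the structural zeros, the
mechanism dichotomy, monotonicities and the sign of the
completeness/gap-fill correlation transfer.

## Numerical choices

* LP/MILP: HiGHS (scipy), primal/dual feasibility 1e-9, MILP
  integrality tolerance 1e-6 (binaries rounded before reporting).
* Variable order is lexicographic in reaction id; with the deterministic
  solver the whole pipeline is byte-reproducible from a master seed.
  Per-model seeds are drawn from the master generator and stay < 2^31.
* Gap-filled fraction = additions / (genome-encoded draft reactions +
  additions); boundary pseudo-reactions are excluded from the
  denominator since they are not genome derived.
* Grid cells: means/s.d. (n-1 denominator) over models whose gap fill
  succeeded; growth fractions count failed gap fills as non-growing in
  the denominator. With the bundled universe the full database always
  restores growth, so infeasible cells arise only with user-supplied
  databases.
* The candidate pool is *not* pruned of exchanges or obviously useless
  reactions; medium bounds already make them worthless, and pruning
  would presuppose the mechanism under test.
* Degenerate inputs: correlation analyses raise on constant
  completeness; a constant gap-filled fraction reports rho = 0.

## Known limitations

* Single objective (biomass), no FVA/pFBA/thermodynamics.
* Two compartments; no periplasm, no gene-protein-reaction rules.
* SBML import is best-effort (species/reactions/bounds/objective);
  round-tripping through the native JSON dialect is lossless, SBML
  preserves structure and bounds but infers reaction kinds when the
  package's annotations are absent.
* The omission mode requires growth on the full medium and is undefined
  otherwise, by construction.
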