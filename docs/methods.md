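# Methods

## Free-Wilson additive model

The model writes a congeneric ligand's activity as a scaffold baseline plus
one independent contribution per (site, substituent) pair,

    pIC50_i = mu + sum_s beta[s, g_i(s)] + eps_i ,

with pIC50 = 9 − log10(IC50/nM). Activities are curated before modelling:
replicate measurements of the same *structure* (canonical SMILES identity,
not the id string) are averaged arithmetically on the nanomolar scale and
converted to pIC50 afterwards; rows with unparseable structures or
non-numeric/censored potencies are dropped and counted. Averaging on the
concentration scale (rather than the log scale) was chosen because potency
ranges are reported in nM; the alternative geometric mean changes curated
values by at most the spread of the replicates and can be probed by
pre-transforming the input.

### R-group decomposition

The core is a SMILES pattern with numbered dummy atoms `[*:1]..[*:S]`. A
molecule is decomposed by enumerating **all** substructure matches of the
core (dummies match any atom, including explicit hydrogens after
H-addition), rejecting matches in which a core atom carries a substituent at
an unnumbered position or a substituent bridges two attachment points, and
keeping, among the surviving symmetry-equivalent assignments, the
lexicographically smallest tuple of per-site canonical substituent SMILES.
Unsubstituted positions are encoded as an explicit `*[H]` substituent so
that "no substituent" is a level with its own coefficient. Decomposition and
reassembly (`attach_groups`, via RDKit molzip) are inverse up to this
canonicalization: re-attaching the substituents reproduces the input
molecule exactly, and re-decomposing is idempotent.

On cores with symmetry-equivalent sites (the central ring's two ortho
positions R2/R3 here; also R4/R6 of the phenoxy ring whenever R7 is
hydrogen) a group can legitimately sit at either equivalent site; the
canonical choice makes decomposition deterministic, at the cost that a
site's observed pool can contain groups "drawn" for its symmetric partner.
All downstream counting and fitting operates on the canonical assignments,
which is the only description that is well-defined on molecules rather than
on labelled tuples.

The exact seven-site numbering of the published series' core is only
described graphically in its source, so the shipped
`data/pdl1_scaffold.yaml` (R1 distal phenyl, R2/R3 central ring ortho
positions, R4–R7 phenoxy ring) is a best-effort reconstruction and is
clearly marked as such; any scaffold file in the same format can be
substituted.

### One-hot design and ridge fit

Each matched ligand becomes a 0/1 row with exactly one active column per
site; no reference level is dropped, so within each site the columns sum to
one and the design is rank-deficient by construction. The L2 penalty
absorbs that deficiency (standard Free-Wilson-with-ridge practice);
features are left unstandardized (they are indicators) and the intercept is
fitted unpenalized.

The penalty is selected by **exact** leave-one-out cross-validation computed
in closed form from one SVD of the centered design: for the ridge smoother
with unpenalized intercept, the LOO residual is `(y_i − ŷ_i)/(1 − h_ii)`
with `h_ii = 1/n + Σ_j d_j U_ij²`, `d_j = s_j²/(s_j²+α)` — an identity, not
an approximation, which the tests verify against explicit refits to 1e−8
and against scikit-learn's RidgeCV. The default grid is 17 points
log-spaced over 1e−4..1e4; exact ties in LOO error resolve to the smallest
alpha (least shrinkage). Reported metrics are in-sample Pearson R and R²
(the convention used when a single "regression model" quality is quoted for
Free-Wilson fits), with the cross-validated LOO-R² always computed
alongside; for a constant response the metrics are undefined and flagged.

**Identifiability.** Adding a constant to all of one site's coefficients and
subtracting it from the intercept changes nothing observable, so absolute
coefficients are identified only up to a per-site offset. Predictions and
within-site coefficient *differences* are identified, and every recovery
test is phrased in those terms. The coefficient report flags singleton
substituents (one occurrence) as low-support.

### Virtual library

The library over the training pools has `prod_s |pool_s|` combinations;
subtracting the observed combinations gives the unexplored count — pure
integer arithmetic, O(1) memory, no enumeration. Enumeration is a lazy
generator in lexicographic pool-index order (or seeded uniform sampling
without replacement), scoring each combination as intercept plus
coefficients and yielding those at or above the potency threshold.
"Unexplored" means combination-level exclusion of the training tuples
(an `include_observed` flag restores the full product). Counts are
tuple-based: on a symmetric core two tuples may assemble to the same
molecule, exactly as in the published 76M-molecule figure this mirrors.
When a scaffold is supplied each yielded combination is assembled and
sanitized; combinations producing invalid chemistry are skipped and
tallied, so the stream only ever contains real molecules.

## Hydration-site scoring

Inputs are per-site summaries of restrained-MD solvent mapping (GIST +
hydration-site analysis): occupancy in [0,1], solute–water energy `E_sw`,
water–water energy `E_ww` already halved to avoid double counting, and
single-body translational/orientational entropy terms that are `T·ΔS`
products in kcal/mol (temperature never appears explicitly). Derived
quantities:

    Etot  = E_sw + E_ww
    TStot = TS_trans + TS_orient
    dH    = E_sw + 2 (E_ww − E_bulk)
    dG    = dH − TStot
    Kss   = occupancy (Etot − E_bulk),   E_bulk = −9.565 kcal/mol/water (TIP3P)

Three conventions deserve note:

* The displacement score is implemented as occupancy × (Etot − E_bulk),
  i.e. the bulk reference is *subtracted as the negative number it is*
  (equivalently, 9.565 is added). A literal reading that subtracts +9.565
  contradicts every row of the packaged reference table; the implemented
  reading reproduces all 28 scores within the rounding of the 2-decimal
  inputs. `e_bulk` is configurable.
* `Kss = 0` classifies as *unfavorable* (displaceable); only strictly
  negative scores mark hard-to-displace water.
* `dG` uses TStot = trans + orient. Whether the entropy in the free-energy
  expression should include both single-body terms or the translational one
  alone is ambiguous in the method's usual presentation; both are computed,
  the sum is the default. Likewise the factor 2 in `dH` is implemented
  verbatim even though `E_ww` is already half-counted; with the default
  bulk reference this can make strongly water–water-stabilized sites (e.g.
  W2) show positive per-water excess enthalpy. Kss, which drives the
  classification and ranking, does not depend on `dH`.

The packaged reference table (`fwsolv/data/pdl1_hydration_sites.csv`)
contains the 28 published per-site rows for the apo human PD-L1 surface
(100 ns restrained TIP3P simulation, CPPTRAJ HSA output) together with the
published Etot/TStot/Kss columns for regression testing. The accompanying
text mentions 32 potential sites while the table prints 28 rows; the
fixture contains the 28 printed rows and the discrepancy is simply
recorded here. Because inputs are printed to two decimals, recomputed sums
match to ±0.015 and Kss to ±0.05, and the recomputed ranking reproduces
the printed order except where two scores tie within that rounding (W3 vs
W13: recomputed 0.549 vs 0.540 against printed 0.51 vs 0.52).

## Synthetic data

`generate_series` draws distinct substituent combinations uniformly without
replacement (seeded), assembles each into a real molecule on the scaffold,
and sets pIC50 = intercept + Σ true contributions + N(0, σ). Ground truth
is expressed in the canonical site assignment and duplicate molecules
(possible only through core symmetry) are dropped. Two profiles:

* **toy** — 3-site phenylpyridine core, pools of 5/6/4 substituents
  (120 combinations), intercept 6.5, per-contribution scale 1.0 (hydrogen
  pinned at 0, comparable to the −1.2..+1.7 coefficient range seen in real
  series of this kind), default σ = 0.1 and n = 60. The ring nitrogen keeps
  all three sites distinguishable so tuple counts equal molecule counts.
* **paper-scale** — the reconstructed 7-site core, pools of
  4/3/3/4/4/3/4 (12,096 combinations), intercept 6.2, contribution scale
  0.5, σ = 0.22 and n = 403: simulated pIC50 spans ≈ 4.5–8.5 and an
  additive ridge fit attains in-sample R² in the low 0.9s, the regime of
  the measured series this emulates.

`generate_hydration_table` draws occupancies from U(0.25, 1) and total
energies alternating between 0.2–1.2 kcal/mol above the bulk reference and
0.3–4.5 below it, split into solute–water and water–water parts, with
entropy terms small relative to the energies — so any table of ≥ 4 sites
contains both favorability classes and round-trips losslessly through the
CSV reader/writer.

What the synthetic series deliberately **lacks**: activity cliffs,
site–site interaction terms, heteroscedastic assay noise, censored values,
and non-random exploration of the combination space. Passing recovery
tests therefore demonstrates correctness of the machinery under the
additivity assumption, not that real SAR is additive — on real data the
LOO-R² gap is the diagnostic for that assumption.

## Problem sizes and determinism

The test suite and the acceptance script run on the toy profile (n ≤ 120)
plus one paper-scale synthetic fit (403 ligands, ~30 columns) and the
28-row hydration table; the whole acceptance run recomputes everything from
scratch in well under a minute. Fitting is deterministic linear algebra
(SVD); the only randomness anywhere is the named seed of the generators and
of the optional library subsampling. Tolerances in tests come from the
sources of error they check: 1e−6/1e−8 for linear-algebra identities,
±0.015/±0.05 for quantities limited by 2-decimal printed inputs.
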