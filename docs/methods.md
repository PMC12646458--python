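# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of the package, stage by stage.

## Structure model and geometry

Structures are parsed with gemmi (PDB and mmCIF) into a minimal
chain/residue/atom hierarchy. All coordinates are Å and are never truncated
internally; the PDB writer emits the format's 3-decimal precision, which
bounds round-trip error at 5·10⁻⁴ Å.

*Altlocs*: only the highest-occupancy conformer of each atom is kept, with
ties resolved toward altloc 'A'. This gives a deterministic single-conformer
model, which is all the downstream scoring needs. *Multi-model files*:
only the first model is read unless all models are requested (multi-model
PDB is also accepted as a trajectory format by the lipid module).
*Hydrogens* are retained on read but excluded from scoring, since predicted
models carry none.

Superposition is the closed-form Kabsch solution (SVD with a determinant
correction that guarantees a proper rotation). Collinear point sets are
rejected rather than silently returning one of the infinitely many optimal
rotations. The test suite checks the Kabsch RMSD against an independent
quaternion-eigenvalue (Horn) implementation to 10⁻⁶ Å.

Residues are paired across structures by (chain id, author number,
insertion code); no sequence alignment is performed. This is the correct
behavior for comparing states of the same deposition and for synthetic
pairs, and it fails loudly (rather than guessing) when numbering schemes
differ.

## Interface scoring (in silico pulldown)

pDockQ uses the published sigmoid parameterization
(0.724, 0.052, 152.611, floor 0.018) with x = mean interface pLDDT ×
log10(number of interface contacts), and the 8 Å Cβ contact rule (Cα for
glycine). The floor 0.018 is reported for contact-free complexes by
convention. The scorer refuses structures not flagged as predicted, because
the B-factor column must hold pLDDT for the score to mean anything.

The clashscore is a heavy-atom approximation of MolProbity's statistic: no
hydrogens are added and no side-chain flips are attempted. A clash is a
non-bonded heavy-atom pair with vdW overlap > 0.4 Å (radii C 1.70, N 1.55,
O 1.52, S 1.80, P 1.80, default 1.70 Å for unknown elements, with a
warning). Bond exclusion is connectivity-free and deterministic: pairs
within one residue, the peptide-bond backbone pairs C–N, C–CA, O–N, CA–N of
sequence-adjacent residues, and any pair closer than 1.2 Å (assumed
covalent-record error) are skipped. Because hydrogens are omitted the
absolute values differ from MolProbity's; the screen uses the score only to
rank candidates, which is robust to a common offset. The neighbor search
(cKDTree within the maximum possible clash distance) is verified against an
O(n²) brute-force enumeration.

Screen ranking computes exact Pareto fronts on (pDockQ maximized,
clashscore minimized); within a front, entries sort by pDockQ descending
then candidate id. "Hit" designation (front-1 membership plus pDockQ above
a configurable threshold, default 0.5) is report-only — in a real screen
the interesting outlier is picked by inspection of the 2D plane.

## Coevolution Z-analysis

Coupling matrices are read in the plain CCMPred dialect (L whitespace rows
of L floats), symmetrized as (M+Mᵀ)/2 with a warning when asymmetry exceeds
10⁻⁶, and the diagonal forced to zero. Z-scores standardize the raw
couplings of the inter-protein block against that block's own mean and
*population* standard deviation — the block is the complete population of
inter-chain cells, not a sample. A whole-matrix background and an optional
average-product correction are available behind flags, but the inter-block
background without APC is the default. The annotation threshold Z > 10
follows the field's convention for paired-alignment screens.

The synthetic generator fills the matrix with half-normal |N(0, scale)|
noise and sets planted cells to μ + z*·σ of the realized non-planted
background. Default partition sizes are 40+40: a 1600-cell half-normal
background has its expected extreme near Z ≈ 5, so a no-signal matrix stays
below the Z = 6 false-hit line in ≥95% of seeds — the behavior expected of
a negative control (two proteins with no physical interface). At much
larger blocks the extreme-value tail of this simple noise model would cross
Z = 6 routinely; real no-signal screens suppress such extremes through the
heavier machinery of the inference itself, which the generator does not
emulate.

## Conformational metrics

Reporter distances default to Cα–Cα. The built-in reporter table carries
the four published reporters of the YbbAP system: the Ser50–Ser148
nucleotide-binding-domain gaps (8.1 Å at both sites when ATP-bound; 17.2
and 23.6 Å apo) and the Leu403–Leu754 periplasmic-pocket gate (6.6 Å bound,
19.2 Å apo), with a ±0.3 Å acceptance band reflecting the 0.1 Å printed
precision plus deposition rounding. Because the deposition does not state
which copy of the ABC subunit pairs with which, both cross-chain pairings
are enumerated and reported per site.

State comparison superposes the second structure onto the first over a
selection (default: Cα of the chain with the most residues — the large
transmembrane subunit — so the smaller moving parts are measured against
the static body) and reports per-residue Cα displacements for all common
residues. Displacements are invariant to pre-applied rigid motions of
either input.

## Lipid analytics

The trajectory container is a flat topology table (name, element, resname,
resid, segment) plus an (frames × atoms × 3) coordinate array in Å with
time in ns. I/O goes through MDAnalysis (GRO/PDB topologies; XTC, DCD or
multi-model PDB frames). Segments are classified from residue names
(standard amino acids → protein; water/ions → solvent; everything else →
lipid), which handles both atomistic and coarse-grained naming via the
headgroup-atom configuration (default reference atom "P", the phosphate).

*Leaflets*: the per-frame midplane is the mean z of all lipid headgroup
reference atoms; a lipid is upper iff its headgroup is strictly above the
midplane (exact ties go lower, with a warning). *Residency*: 30 × 30 bins
of 2.5 Å (a 75 Å window) centred on the protein's time-averaged xy
centroid, counting headgroups of one lipid type in one leaflet over strided
frames (default stride 10, mirroring 1 ns frames sampled every 10th);
observations outside the window are dropped and counted, so
counts + dropped always equals the total observations. Density is
normalized to the per-grid maximum by default; normalizing a set of grids
to their global maximum is supported when plots are to share a scale.
*z-traces* are measured against the midplane by default; measuring against
the upper-leaflet phosphate plane is a flag, since either convention is
defensible for extraction events. *Contact propensity* uses integer frame
arithmetic — (frames with any heavy-atom pair < 4 Å) / (frames analyzed) —
so planted schedules are recovered exactly. *RMSF/RMSD* superpose each
frame on the first over the protein backbone before measuring; RMSF is the
per-atom fluctuation about the mean position, averaged within residues.
For isotropic Gaussian jitter of scale σ per coordinate the per-atom RMSF
is σ√3, which the tests verify to 5% at 1000 frames.

No periodic-boundary imaging is performed beyond what the generator plants;
the module is an analysis layer, not a simulation engine.

### What the synthetic trajectories do and do not emulate

The generator builds a two-leaflet slab (headgroup planes at ±17 Å) around
a static dummy protein: a jittered backbone column plus a noise-free ring
of six pocket-lining residues at the upper headgroup plane. One tagged
LysoPG follows a planted schedule — a known fraction of frames with its
headgroup exactly at the pocket centre, optionally a linear z-rise
emulating an extraction event — while all other lipids are resampled
uniformly per frame. The planted-signal atoms (tagged lipid, pocket ring)
are exempt from thermal jitter so the manifest's occupancy and contact
schedules are exact rather than statistical. Consequently the tests
demonstrate that the *analytics* recover planted statistics faithfully;
they say nothing about force fields, diffusion, or sampling convergence of
real simulations, and trajectory realism (lipid dynamics, PBC artifacts,
protein flexibility) is explicitly out of the generators' scope.

Problem sizes used in tests and in the acceptance script (100–1000 frames,
~100 lipids, 40+40-residue coupling matrices, 500-atom clash structures,
100-replicate kinetics studies) were chosen as the smallest sizes at which
the statistical properties under test are comfortably resolved.

## Kinetics

Initial rates are OLS slopes over the first 20% of points (minimum 5); the
window is configurable because instruments and lag phases vary, and a
paired blank curve on the same time grid is subtracted when supplied.
Wavelengths (400 nm for p-nitrophenyl esters, 496 nm nitrocefin, 420 nm
DTNB) are metadata only; conversion to molar units is behind an optional
extinction-coefficient parameter.

The Michaelis–Menten fit uses scipy's Levenberg–Marquardt/TRF nonlinear
least squares with Vmax₀ = max v and Km₀ = the S at the first v ≥ Vmax₀/2,
non-negative bounds, and asymptotic standard errors from the Jacobian at
the optimum (no bootstrap by default). The fit is scale-equivariant in S.
When the fitted Km falls below the smallest assayed concentration the
result carries a saturated-regime flag with km_upper_bound = min(S): in
that regime the rate is Vmax at every assayed S and the data cannot locate
Km, only bound it — the honest report for an enzyme with nM-scale Km
assayed at µM substrate. The synthetic rate generator floors rates at zero
(a spectrophotometric rate readout is non-negative), which introduces
negligible bias at the 5% noise level used in the recovery study.

Relative activities are percent of the reference-group mean with standard
deviations scaled by the same factor, reported with replicate counts
(default study design: six replicates, as two biological × three technical
repeats).

## Known limitations

- The clashscore is hydrogen-free and will not match MolProbity absolutely.
- The coevolution module consumes coupling matrices; alignment pairing and
  the coupling inference itself are upstream.
- Leaflet assignment by midplane sign misclassifies lipids mid-flip; none
  of the planted data exercise flip-flop.
- The saturated-regime Km flag is a detection heuristic (Km̂ < min S), not a
  formal identifiability test.
- Synthetic generators plant statistics, not physics (no force fields, no
  energetics, no realistic chain geometry beyond what the scoring rules
  need).
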