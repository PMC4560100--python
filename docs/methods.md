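# Methods

## The repeat-swap procedure

An inverted-topology transporter contains two repeat units RU1 and RU2
related by a two-fold pseudo-symmetry whose axis lies in the membrane
plane.  In any one conformational state the repeats are *asymmetric* —
each adopts its own internal/relative conformation — and exchanging the
two conformations produces the state open to the opposite side of the
membrane.  The pipeline operationalizes this:

1. **Repeat definition** (input, never inferred).  Automatic internal-
   symmetry detection is unreliable for asymmetric, low-identity repeats,
   so repeat and domain boundaries are always user-supplied residue
   ranges in author numbering.  Published definitions for Glt_Ph and
   VcCNT ship as presets.
2. **Structural alignment of the repeats** (`align_repeats`).  A
   sequence-independent alignment: gapless threadings of the two Cα
   traces are ranked by superposition quality; the best few seed an
   iteration of (Kabsch superposition on current pairs) → (score every
   inter-Cα distance with the TM-score local term `1/(1+(d/d₀)²)`) →
   (dynamic-programming re-alignment) until the pair list is stable, at
   most 30 rounds; the highest-TM pairing wins.  Non-convergence returns
   the best iteration with a warning.
3. **Swap alignment** (`build_swap_alignment`).  The pairwise alignment
   is duplicated into a full-length target↔template alignment: target RU1
   columns pair with template RU2 residues, target RU2 with template RU1
   (the transposed pairing), peripheral segments (present in the
   structure but in neither repeat) pair with themselves gaplessly, and
   linkers get all-gap template columns.
4. **Refinement** (`refine_alignment`).  Gap runs that open inside
   template helices are relocated to the nearest non-helical column
   within the same block (N-terminal side on ties), skipping the
   structural all-gap linker columns, and only when the move preserves
   the aligned-pair count; conservation input produces advisory
   diagnostics only, since burial-vs-conservation judgments are a
   human-in-the-loop step.
5. **Swapped template** (`assemble_swapped_template`).  The coordinate
   file is re-ordered RU2-first.  Because the model is "upside-down"
   relative to the template, peripheral fragments are reoriented by
   superposing the input structure's RU1 onto the RU1 of an initial
   (peripheral-free) model and applying that transform; the residues are
   renumbered consecutively with the old→new map kept as provenance
   (REMARK 300 lines in the written file).
6. **Model building**.  The `build_naive_model` coordinate-transfer
   builder copies each aligned template residue's backbone onto the
   target residue and linearly interpolates unaligned residues (marked
   occupancy 0.0).  It is deterministic and dependency-free; it is *not*
   a substitute for restraint-based comparative modeling — for that,
   `emit_modeling_inputs` writes a complete Modeller bundle.
7. **Restraints**.  Gaussian distance restraints with σ = 0.1 Å: every
   intra-domain Cα pair strictly closer than 60 Å (scaffold and transport
   domains independently, never across the boundary — the inter-domain
   motion is the prediction), plus ligand restraints (ligand heavy atom ↔
   protein heavy atom strictly within 5 Å, or 3.5 Å for the tight scheme,
   or explicitly named coordination pairs which may include a
   crystallographic water).  Targets equal observed distances.
8. **Motion analysis** (`analyze_change`).  Superpose model and reference
   on scaffold Cα; Kabsch-fit the residual transport-domain transform;
   decompose into rotation angle (from the rotation-vector norm, in
   [0, 180°]), axis, and centroid displacement expressed in the membrane
   frame; report per-domain RMSD/TM-score and a per-residue Cα
   displacement profile.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| Cα restraint cutoff | 60 | Å | preserves whole-domain internal packing; beyond this pairs add nothing within a compact domain |
| restraint σ | 0.1 | Å | tight Gaussians: restraints should reproduce, not merely bias toward, the observed geometry |
| ligand shell | 5 (tight: 3.5) | Å | first coordination shell of a bound substrate/ion |
| DP gap open / extend | 0.6 / 0.2 | TM-local score | see "Numerical choices" |
| TM-score d₀ clamp | 0.5 | Å | the d₀ formula is negative below L≈21 |
| model iterations | 200 / 2000 | – | refinement rounds vs restrained stages of the emitted Modeller run |
| toy asymmetry | 20° / 5 Å | – | a mid-sized elevator swing: larger than VcCNT's (~12°, 3–4 Å), well under Glt_Ph's (~40°, 16 Å) |
| toy noise_A | 0.1 | Å | coordinate jitter of the order of crystallographic uncertainty at ~3 Å resolution |

## The synthetic generator: what it emulates and what it does not

`make_toy_transporter` builds a Cα-only poly-alanine fold: per repeat,
alternating up/down α-helices (1.5 Å rise, 100° twist, 2.3 Å radius) with
3-residue straight linkers; RU2 is RU1's exact image under a 180° rotation
about the x-axis (membrane normal = z), so the symmetry operation is exact
by construction.  The transport sub-repeat of RU2 is then swung about an
in-plane axis and shifted along the normal; the swapped-truth conformer
carries the conjugate swing (symmetry ∘ swing ∘ symmetry) on RU1 instead.
The recorded ground-truth motion is the exact Kabsch fit of the noiseless
transport-domain Cα between the original and swapped-truth structures —
pure bookkeeping, independent of the pipeline under test.

Helices are given a gentle constant-curvature bend (radius 45 Å, bend
plane rotated per helix).  This is deliberate: a perfectly straight ideal
helix is nearly invariant under a one-helical-turn screw shift, so repeat
alignment of straight-helix toys is register-ambiguous in a way real,
bent, side-chain-bearing TM helices are not.  The bend magnitude (~25°
total arc over an 18 Å helix) is at the curved end of real TM helices.

Not emulated: side chains and sequence divergence (both repeats are
poly-alanine, so the toys cannot probe sequence-based alignment cues or
conservation-guided refinement), realistic loop geometry (linkers are
straight segments with sub-peptide Cα spacing), multi-chain assemblies,
and crystallographic artifacts beyond isotropic jitter.  Passing tests
therefore demonstrate that the *geometric* protocol — alignment,
duplication, swapping, restraint generation, motion recovery — is
correct; they do not measure the sequence-refinement quality attainable
on real proteins.

## Numerical choices

* **Gap costs.**  The DP gap penalty acts on the TM-local score (each
  matched column contributes ≤ 1).  With a pure opening cost (extend =
  0), shifting an entire helix by 1–4 residues costs only one opening and
  is often score-optimal under the compromise superposition of two
  asymmetric repeats — the one-turn screw degeneracy.  A nonzero
  extension cost (0.2) makes an L-column gap cost grow with L, restoring
  the gapless true register as the optimum while leaving genuine
  length-difference gaps affordable.  Both parameters are exposed.
* **Secondary-structure fallback.**  When no DSSP output is supplied,
  helices are assigned from Cα geometry: i→i+3 distance 5.1 ± 0.6 Å *and*
  consecutive Cα distances 3.8 ± 0.6 Å over runs of ≥ 4 residues.  The
  second condition rejects compact non-peptide-spaced geometries whose
  span accidentally matches the helical rise.
* **TM-score search.**  Contiguous fragment seeds of length L, L/2, L/4
  at every offset, each refined by the standard distance-cutoff inclusion
  iteration (cutoff d₀, grown in 0.5 Å steps until ≥ 3 pairs survive) to
  convergence, max over all seeds; for ≤ 10 residues every subset of size
  ≥ 3 is seeded, making the tiny-input search exhaustive (and testable
  against an independent enumeration oracle).
* **Decomposition conventions.**  Rotation angle from the rotation-vector
  norm (always in [0, 180°]; near 180° this reduces to the dominant
  eigenvector of the symmetric part).  The axis-vs-membrane angle is
  folded into [0, 90°] since the axis sign is not physical.  The centroid
  displacement is the transport-domain Cα centroid under the fitted
  transform minus itself, expressed in an orthonormal frame completed
  deterministically from the membrane normal (x̂ projected into the
  plane, else ŷ); only the normal component and the in-plane magnitude
  are basis-independent, and cross-study comparisons should use those.
* **Per-domain RMSD/TM.**  Each domain's similarity is its *own*
  least-squares superposition RMSD (and TM-score, which optimizes its own
  superposition).  The scaffold-fitted pose is used for the displacement
  profile — there a transport-domain value of ~16 Å *is* the result, not
  an error.
* **Membrane frame.**  Default: normal = z (OPM-oriented input).  For
  deposited, non-oriented trimers, `membrane_frame_from_trimer` uses the
  rotation axis of a protomer-onto-protomer superposition (the three-fold
  axis) as the normal.
* **Degenerate inputs.**  Superposition requires ≥ 3 non-collinear
  points; altlocs resolve to highest occupancy with alphabetical
  tiebreak; strict inequalities at restraint cutoffs (a pair at exactly
  60 Å is excluded); empty residue selections are legal but carry a
  missing-count warning in provenance.

## Design choices where the design was open

* **Addressing.**  Author numbering is the only residue addressing scheme
  exposed; published domain definitions are author-numbered, and silent
  renumbering is the classic source of off-by-N modeling errors.  All
  renumbering is explicit and leaves a provenance map.
* **Peripheral reorientation** uses the full RU1-onto-RU1 Cα fit.  Under
  strong asymmetry this fit is contaminated by the moving sub-repeat, so
  the reoriented peripheral position is approximate — by design it is
  corrected later by restraints during model building.
* **Refinement is conservative.**  Gap relocation never crosses block
  boundaries and never changes the aligned-pair count; anything it cannot
  fix becomes a diagnostic rather than a silent edit, mirroring the
  protocol's human-in-the-loop character.
* **Model orientation.**  The naive model is reported both raw (template
  frame, upside-down) and oriented by superposition onto the input
  structure, the convention for placing models in the input's membrane
  frame.

## Problem sizes

The test-bed and the acceptance script use toys with 4 helices of 12
residues per repeat plus one peripheral helix (132 residues), 20 seeds
for the end-to-end sweep, and 50 random fixtures (8–70 residues) for the
restraint-count oracle.  These sizes keep the whole suite in the
tens-of-seconds range while leaving every stage non-trivial (split
domains, peripheral reorientation, register-ambiguous helices).

## Known limitations

* The naive builder transfers backbone coordinates only; side chains
  beyond Cβ, loop closure and stereochemistry are left to Modeller.
* `align_repeats` assumes the repeats are globally superposable up to
  moderate internal asymmetry; toys with ≥ 6 helices per repeat and large
  swings can still misregister a helix (the same regime where real
  applications rely on conservation-guided manual refinement).
* Restraint generation includes repeat-internal Cα pairs already implied
  by the template; the redundancy is harmless for Gaussian restraints but
  the counts are correspondingly larger.
* Multi-chain repeat units and mmCIF input are out of scope; structures
  are analyzed one protomer at a time.
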