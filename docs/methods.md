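# Methods

This note records the modelling and numerical decisions behind minifold:
what each component assumes, which defaults matter and why they were
chosen, what the synthetic data does and does not emulate, and the known
limitations. Nothing here states an empirical result beyond what the test
suite and `scripts/acceptance.py` themselves compute.

## Representations and conventions

* **Units.** Ångström for all coordinates and distances; degrees for all
  angles at API boundaries (radians internally). Activations are unitless.
* **Frames.** A residue frame is a proper rotation plus translation built
  from the N, CA, C atoms by Gram–Schmidt: origin at CA, first axis along
  CA→C, second axis the orthogonalized CA→N component, third their cross
  product (right-handed). Rotations are stored as 3×3 matrices, which makes
  the invariance tests direct; a quaternion parameterization is used only
  where frame *updates* are predicted, with the real part fixed to 1 so
  that a zero prediction is exactly the identity.
* **Degeneracy.** Three points whose enclosed angle has sine < 1e-6 (or
  coincident points) raise an explicit degenerate-frame error rather than
  propagating NaNs.
* **Alphabet.** 20 amino acids + X (unknown) + gap + MASK = 23 input
  classes; masked-MSA reconstruction is over the 22 non-MASK classes.
* **Atom layout.** Dense per-residue heavy-atom arrays of width 14
  (tryptophan's heavy-atom count), with an existence mask; masked atoms
  never enter any loss or metric. Ideal residue geometry and intra-residue
  bond graphs come from the Chemical Component Dictionary bundled with
  biotite; χ-rotatability is derived from the bond graph (removing a χ
  axis must disconnect the side chain, which correctly marks proline's
  ring torsions as non-rotatable).

## Trunk (Evoformer)

Each block applies, with residual connections and pre-layer-normalization:
pair-biased MSA row attention, MSA column attention, MSA transition,
outer-product mean into the pair stack, triangle multiplicative updates
(outgoing, then incoming), triangle self-attention (starting, then ending
node), pair transition. Notable choices:

* **Widths.** Full-scale defaults c_m=256, c_z=128, c_s=384, 48 blocks,
  8 MSA / 4 pair heads, transition widening 4. Everything is configurable
  down to c=8; the test configurations use `ModelConfig.toy()` (2 blocks,
  c_m=32, c_z=16).
* **Zero-initialized output projections.** The final linear layer of every
  residual branch starts at zero, so a freshly initialized block is the
  identity map. This is the standard stabilization for deep residual
  trunks and gives the tests a sharp reduction property.
* **Gating.** Sigmoid gates with bias initialized to one (gates start
  open). The triangle multiplicative update's hidden width equals c_z.
* **Ending-node triangle attention** is implemented as the starting-node
  update on the transposed pair representation, which reproduces the
  defining logits q(z_ij)·k(z_kj) + b(z_ki) exactly and is verified
  against a loop-written oracle.
* **Relative positions.** Pair initialization adds a one-hot encoding of
  the sequence offset clipped to |i−j| ≤ 32.
* **Masking.** Optional residue/sequence masks exclude padded entries from
  every softmax and from the outer-product mean; a leakage test asserts
  masked residues cannot influence unmasked outputs.
* **Cluster featurization** after subsampling is minimal: the centre rows
  themselves (one-hots + deletion features) are embedded; no profile of
  the assigned extra sequences is added. This is an approximation adequate
  at desk scale.

## Structure module

* The residue gas starts at identity rotations and origin translations.
  Eight shared-weight iterations at full scale (4 in the toy config) of
  IPA → layer-norm → transition → frame update. No chain constraint is
  enforced anywhere; a test asserts predicted peptide bonds can be broken
  before any violation penalty is applied.
* **IPA.** 8 heads, 4 query points, 8 value points by default (2/2/2 in
  toy configs). Logits combine the scalar query–key term (scaled 1/√d),
  a pair-bias projection, and a softplus-positive per-head weight γ times
  the negative squared distances between query and key points in the
  global frame; the three terms share the standard √(1/3) balance and the
  point term the √(2/(9·P_q)) normalization. The output concatenates
  attended scalar values, attended pair values, attended points mapped
  back to the local frame, and (by default, flag-controlled) those points'
  norms.
* **Frame update.** Six numbers per residue: a local translation (scaled
  by 10 Å per unit so the gas can traverse protein-sized distances early
  in training) and the quaternion vector part. Gradients through the
  rotations are stopped between iterations by default (config flag) for
  training stability; translations stay fully differentiable.
* **All-atom build.** Residue templates are posed in each frame; for each
  valid χ slot the atoms downstream of the axis are rotated so the
  dihedral equals the requested angle, which makes torsion extraction an
  exact inverse (round-trip verified to 1e-4°). The carbonyl O is then
  re-placed from the actual ψ geometry (trans to the next residue's N),
  since its template position is only valid for the template's own ψ.

## Losses and heads

* **FAPE**: clamped L1 over all frame-aligned atom distances,
  d_clamp = 10 Å, normalization Z = 10 Å, with a small ε inside the square
  root for differentiability. Invariant to global rigid motion of either
  side; *not* invariant to mirroring — the chirality test requires the
  mirrored prediction of a non-planar structure to score strictly worse.
  (An ideal β-strand is close to planar and hence nearly achiral; the
  chirality sweeps use helix and mixed motifs.)
* **Distogram**: 64 bins spanning 2–22 Å on Cβ (Cα for glycine), last bin
  catch-all; logits symmetrized; diagonal excluded.
* **pLDDT**: 50 bins of width 2 on [0, 100]; the confidence is the
  expectation of bin centers; the training target is the binned true
  per-residue lDDT-Cα computed by the metrics module.
* **Pairwise error / pTM**: 64 bins spanning 0–32 Å. The representative
  error of a bin is its *lower edge*, so a prediction concentrated in the
  zero-error bin attains the kernel's value at zero, i.e. pTM = 1 exactly;
  d0(L) = 1.24·(L−15)^⅓ − 1.8 floored at 0.5.
* **Torsion loss**: squared chordal distance on the unit circle between
  predicted and true (sin, cos); χ slots with 180°-symmetric terminal
  groups (Asp χ2, Glu χ3, Phe/Tyr χ2) are scored against the nearer image.
* **Violations**: flat-bottom (zero inside tolerance, linear outside) on
  the peptide C–N length (1.329 ± 12 σ, σ = 0.014 Å), the CA–C–N and
  C–N–CA angles (± 12 σ, σ = 2.0°/2.5°), and non-bonded heavy-atom clashes
  below the sum of van der Waals radii minus a 1.5 Å allowance. Active
  only in the fine-tune configuration.
* **Loss weights** (one config block): FAPE 1.0 dominant; distogram,
  masked-MSA and torsion 0.3 each; pLDDT 0.01; violation 0 (0.1 in the
  fine-tune config). FAPE is averaged over the structure module's
  iterations and over recycling passes.

## Recycling and training

The loss is applied to every recycling pass's outputs, with re-injected
features detached, so gradient cost stays that of a single pass; inference
returns only the final pass. Re-injected features — previous pair
representation, previous first MSA row (both layer-normalized through
zero-initialized projections) and a 15-bin one-hot embedding of previous
pseudo-Cβ distances (3–21 Å) — are each independently switchable for
ablations; zeroing all three provably reduces recycling to a repeated
single pass.

The toy trainer uses single-example steps, contiguous crops (256 at full
scale, 64 in toy configs), inverse-cluster-size example sampling,
BERT-style MSA corruption (12% MASK + 3% mutate per entry), and Adam at
3e-3 with cosine decay to a tenth over the run. These are conventional
choices for a small adaptive-moment setup; only toy-scale convergence is a
supported claim. Divergence (non-finite loss) raises an explicit error
with the per-term breakdown. All randomness flows from one integer seed.

Problem sizes used by the tests and the acceptance script — 16-residue
chains, 8-sequence MSAs, 2-block trunks, up to 2,000 training steps — were
chosen so the full validation cycle runs on a single CPU in minutes while
still exercising every code path at realistic tensor ranks.

## Metrics

* **lDDT** is superposition-free; the inclusion set (pairs within 15 Å,
  different residues) is defined by the *true* structure, which makes the
  score asymmetric in its arguments (asserted by a constructed
  counterexample). Thresholds 0.5/1/2/4 Å; per-residue scores count each
  pair for both endpoints.
* **GDT** (thresholds 1/2/4/8 Å) and **TM-score** maximize over
  superpositions. For chains of ≤ 10 residues the maximum is computed
  exactly by enumerating every alignment subset of size ≥ 3 (cheap with
  memoized per-subset superpositions). Longer chains use a deterministic
  heuristic — contiguous-window and 3-residue seeds, best-k prefix
  extension on the error ranking, then 1-exchange hill climbing with a
  lexicographic objective whose continuous tie-break walks count plateaus
  — whose gap against enumeration is bounded in the tests at the
  crossover length. Small-instance enumeration exists because constructed
  adversarial cases show the subset landscape can hide optima from any
  local search.
* **rmsd95** follows the literal 5-iteration procedure: align on the
  current set (all Cα first), re-select from *all* atoms the 95% with the
  lowest error, and report the RMSD of the final selection. Re-selection
  from all atoms each iteration is the closest literal reading of the
  procedure; requires ≥ 20 Cα.
* **Rotamer accuracy**: a χ is correct within 40° circular difference,
  symmetric slots via the nearer image.

## Synthetic data: what it does and does not emulate

`make_toy_structure` builds chains with ideal bond lengths/angles, ω=180°,
and canonical motif torsions (helix −57°/−47°, strand −120°/120°, mixed
with two extended transition residues before each boundary so the chain
opens up instead of colliding with its own turn). Side chains sit at
canonical extended rotamers (χ1 = −60°, distal χ trans, aromatic χ2 = 90°),
with a deterministic greedy rotamer search resolving any residual steric
clash, so generated structures satisfy `violation_loss == 0` by
construction. Default random sequences exclude proline (a helix breaker
whose ring constrains φ, which an idealized motif backbone cannot honour);
explicit sequences may include it. `make_synthetic_msa` applies i.i.d.
substitutions and gaps per position.

None of this reproduces real evolutionary covariation, indel structure,
rotamer–backbone coupling, crystallographic noise, or multi-domain
packing. Passing tests therefore demonstrate that the machinery is
*correct* (invariances hold, losses have their defining geometry, training
can recover structure from signal present in the inputs) — not that the
architecture trained on real data at this scale would be accurate.

The chain-curation rules (`filter_chain_records`) operate on generic
metadata records, applied in the narrative order of their definition:
release-date cutoff, single-residue-type sequences, ambiguous chemical
components (operationalized as any non-standard residue code),
exact-duplicate deduplication keeping the most resolved Cα, < 16 resolved
residues, unknown residues, NMR entries, best resolution per cluster,
< 80 resolved Cα, > 1,400 residues. Per-rule attrition counts sum to the
total by construction.

## Known limitations

* No templates, no ensembling (model selection over independently seeded
  models by mean pLDDT, optionally pTM, is provided instead), no
  post-prediction force-field relaxation, no separate deep-MSA stack.
* The autodiff engine is tape-based pure Python/numpy: ideal for clarity
  and CPU-scale experiments, not for large-scale training.
* All-atom FAPE is not used for training (backbone FAPE + torsion loss
  stand in for it); the all-atom build is exact but non-differentiable.
* Proline side-chain torsions are treated as fixed template geometry.
* Terminal chemistry (OXT), alternate conformers beyond
  highest-occupancy selection, and hydrogens are out of scope.
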