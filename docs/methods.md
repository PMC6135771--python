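# Methods

`hairpinmc` studies the folding thermodynamics of three 16-residue
β-hairpins — the C-terminal hairpin of the protein G B1 domain (GB1p,
`GEWTYDDATKTFTVTE`) and two designed variants, HP5A (`KKYTWNPATGKATVQE`)
and GB1m3 (`KKWTYNPATGKFTVQE`) — with replica-exchange Monte Carlo (REX-MC)
sampling of two in-package models, followed by the standard two-state
analysis used for hairpin folding. The two variants replace the flexible
-DATK- loop with a proline-rigidified -PATG- loop; HP5A additionally weakens
the cross-strand hydrophobic pairs (Trp→Ala, Tyr→Val at the contact
positions). This gives three folding regimes: strongly cooperative
two-state folding with a large entropic cost (GB1p), marginal two-state
folding with a small entropic cost (HP5A), and folded-state-dominated,
essentially downhill folding (GB1m3).

## Reaction coordinate and state definitions

The primary reaction coordinate is N_HB, the number of native backbone
hydrogen bonds formed out of the seven-pair registry of the GB1 hairpin
(local residue pairs 2–15, 4–13, 6–11 donor+acceptor each, plus 10NH–7CO).
A registry H-bond counts when the donor-H/acceptor-O distance is ≤ 2.6 Å;
the two native side-chain contacts (positions 3–14 and 5–12) count when
the minimum distance between the side-chain bead groups is ≤ 6.5 Å for the
single-bead coarse-grained side chains (4.2 Å is the conventional heavy-atom
criterion for all-atom inputs and remains available as a parameter).
Frames with N_HB ≥ 4 are folded, N_HB ≤ 1 unfolded; N_HB ∈ {2, 3} are
intermediates and enter neither population.

From the production ensemble at temperature T:

- ΔG = −RT ln(P_f / P_u);
- ΔU = ⟨U⟩_folded − ⟨U⟩_unfolded, total and per energy component;
- ΔS = (ΔU − ΔG)/T — an identity by construction, reported in cal/mol/K in
  physical units;
- T_m is the temperature with P_f = P_u, located by linear interpolation of
  ΔG(T) between the bracketing ladder temperatures (P_f − P_u where ΔG is
  unavailable), with a bound such as "<270" when no crossing is bracketed.

When the unfolded state is essentially unsampled (unfolded-frame count
below a floor of 10, configurable) the estimator switches to a
*folded-dominated* mode: P_u := 1 − P_f in the free energy, and ΔU/ΔS are
flagged as not directly estimable rather than reported from a handful of
frames.

Reported uncertainties follow the half-split convention: each estimate is
recomputed on the first and second halves of the production window and the
standard error is half the absolute difference. For statistical *gating* in
the test suite this 1-degree-of-freedom estimate is too noisy (the true
error exceeds 3×SE roughly 20% of the time by construction), so tests gate
on a batch-means standard error over 20 contiguous batches instead; the
half-split value remains the reported, table-style uncertainty.

## The zipper model (analytic oracle)

The zipper model collapses a hairpin to the integer coordinate N ∈ [0, 7]:
E(N) = −N·ε and degeneracy Ω(N), giving Z = Σ_N Ω(N) e^{βNε} exactly.
Ω encodes conformational (chiefly loop) entropy. The packaged presets use
Ω(N) = exp(s0·(1 − (N/7)^γ)) with, in physical units:

| preset | ε (kcal/mol) | s0 | γ | anchors |
|---|---|---|---|---|
| GB1p-like | 1.6162 | 20.29 | 0.5 | P_f(298 K) = 0.30, ΔS(270 K) = −38 cal/mol/K |
| HP5A-like | 0.2614 | 5.333 | 0.2 | P_f(298 K) = 0.21, ΔS(270 K) = −7.6 cal/mol/K |
| GB1m3-like | 0.7199 | 5.333 | 1.0 | P_f(298 K) = 0.86, s0 shared with HP5A |

s0 is the total entropy (units of R) released on zipping — large for the
flexible loop, small and shared for the two rigid-loop peptides — and γ
sets how front-loaded the entropy loss is. γ = 0.2 for HP5A makes the loss
front-loaded enough that its free-energy profile keeps a barrier ≥ 1 kT at
270 K despite the weak contacts; γ = 1 for GB1m3 makes F(N) exactly linear,
hence strictly downhill whenever ε exceeds RT·s0/7 (true below ~580 K).
Consequences of this calibration: GB1p-like melts at 285 K (literature
bounds ≲278–293 K), HP5A-like at 201 K (consistent with the reported
"<270"/"<273" bounds), while GB1m3-like melts near 583 K — far above the
measured ~333 K. Hitting both P_f(298) = 0.86 and T_m ≈ 333 K requires
Ω(0) much *larger* than GB1p's, contradicting the rigid-loop physics the
degeneracy is meant to encode; the preset keeps the physics and the
population anchor and concedes T_m. At the analysis thresholds the exact
populations give the regime picture directly: at 270 K, F(N_HB)/kT has a
4.8 kT barrier for GB1p-like, 1.25 kT for HP5A-like, and is monotone
decreasing (single folded minimum) for GB1m3-like.

The zipper Monte Carlo move proposes a step to the adjacent state *within
the support of Ω* (zero-degeneracy states carry zero weight and are
skipped), reflecting at the ends by rejection; acceptance is Metropolis on
Ω(N)e^{−βE(N)}. Support-stepping keeps the proposal symmetric and the
chain ergodic even for the two-level model Ω = (g, 0, …, 0, 1), whose
closed forms (T_m = E0/(k_B ln g)) anchor the replica-exchange validation.

## The coarse-grained hairpin model

The chain's degrees of freedom are the 16 CA bead positions. Carbonyl-O,
amide-H and side-chain beads are *derived*: with tangent t (unit vector
between the flanking CAs) and bend normal n (unit bisector towards the
neighbours' midpoint), O = CA + 1.8·n + 0.8·t, HN = CA + 1.8·n − 0.8·t and
SC = CA − 1.0·n. The frame is built purely from CA positions, so every
observable is rigid-motion covariant; on a locally straight chain the
bisector vanishes and the normal offset is dropped (beads collapse onto the
tangent line, correctly scoring zero contacts). Side chains sit on the face
opposite the polar groups, as in a pleated strand.

The potential (kcal/mol) is native-centric:

- harmonic CA–CA bonds (k = 20, r0 = 3.8 Å) and CA angles (k = 1.5,
  θ0 = 143°, the pleated-strand value); a weak cosine dihedral (k = 0.2)
  favouring extended stretches;
- within the loop (residues 6–11), angles and dihedrals are restrained to
  the native turn geometry with force constants 4.0 and 2.0 scaled by the
  dimensionless multiplier λ_loop (flexible -DATK- ⇒ small λ, rigid -PATG-
  ⇒ large λ);
- soft-core excluded volume ε(σ²/(d²+0.25))⁶ between CA pairs ≥ 2 bonds
  apart (σ = 2.5 Å) — finite at zero separation;
- switched attractive wells on the 7 registry HN/O pairs (full depth ε_hb
  inside 2.6 Å, smoothly off at 4.5 Å) and on the 2 side-chain pairs
  (ε_sc, 5.0→8.0 Å);
- an optional Debye-screened charge term (K/R = +1, D/E = −1), off by
  default.

The reference (native) conformation is an idealized pleated hairpin:
strand pleat 0.6 Å, inter-strand gap 4.2 Å, per-residue rise 3.606 Å, and a
two-residue chain-crossing turn positioned so all seven registry distances
equal 1.80 Å — a 0.8 Å margin below the counting criterion, so the folded
basin scores N_HB = 7 robustly against thermal pleat fluctuations.

Moves are symmetric: single-bead Gaussian displacement (σ = 0.35 Å),
crankshaft rotation of an interior segment about the axis through its
anchors, and pivot rotation of one chain end about a random axis (both
uniform in ±0.9 rad). One sweep is 16 attempted moves.

### CG presets and what λ_loop does and does not do

| preset | ε_hb | ε_sc | λ_loop |
|---|---|---|---|
| GB1p-like | 3.0 | 3.0 | 0.25 |
| HP5A-like | 1.3 | 0.9 | 3.0 |
| GB1m3-like | 4.0 | 4.0 | 3.0 |

A direct A/B experiment (identical contacts, λ = 0.05 vs 6.0, two seeds)
showed the loop restraint to be thermodynamically near-neutral in this
model: because the restraint is harmonic about the *native* turn in both
sub-ensembles, it narrows the loop's fluctuations in the coil and in the
folded state nearly equally, and the folded-population shift cancels. The
presets therefore keep the λ structure for its kinetic/structural role
(turn pre-organization), while the net thermodynamic stabilization that
loop rigidification confers in the real peptides is carried by the contact
strengths, calibrated against the qualitative regime targets: folded
population at 270 K ordered GB1m3-like > GB1p-like > HP5A-like, with
GB1p-like near the literature ~65% folded at 270 K. In the same spirit the
weakened HP5A contacts reflect both its smaller hydrophobic pairs and the
net-destabilizing screened electrostatics reported for it.

The CG N_HB distributions are broad (the surrogate-bead criterion adds
geometric noise to the count), so the sampled CG profiles do not show the
crisp bimodal/downhill distinction; that distinction is asserted on the
zipper presets, where it is exact. The CG model covers the
population-ordering half of the regime picture, sampled.

## Replica exchange

Temperatures follow the exponential ladder T_k = T_min(T_max/T_min)^(k/(n−1))
(endpoints exact). Between exchange attempts every replica runs
`exchange_interval` sweeps (default 2, the analog of attempting exchanges
every 2 ps of MD). Attempts alternate between even- and odd-indexed
neighbour pairs, so all disjoint pairs are tried on alternating attempts;
a pair swaps temperatures with probability min(1, exp[(β_i−β_j)(U_i−U_j)]).
The master seed spawns one independent random stream per replica plus one
for exchange decisions, and one uniform variate is consumed per attempt
regardless of outcome, so identical configurations reproduce bit-identical
records independent of execution order. The default production window is
the last 60% of sweeps. The exchange record tracks the
replica→temperature permutation each sweep, every attempt's log-argument
and outcome, per-pair acceptance rates and per-replica round trips.

Hairpin REX runs in the packaged tests and the acceptance script use 5
replicas spanning 270–550 K and 3 500–4 000 sweeps per replica — sizes
chosen so a full three-peptide comparison completes in a few minutes on one
CPU while the two-level-zipper REX validation (8 replicas, 100 000 sweeps)
pins the sampler against closed forms to ~0.5% in P_f.

## Landscapes

Free-energy grids are F = −kT ln p over histogram bins, min-shifted to
zero, with empty bins masked; integer coordinates (N_HB, N_SC) use
unit-width bins centred on the integers, distances default to 0.5 Å bins,
and principal-component axes use range/50. Contours are drawn at every kT.
The "minimal energy path" between two basins is defined as the
bottleneck-optimal path over 8-connected unmasked bins — it minimizes the
maximum F along the path, with ties broken by the smaller summed F and
then lexicographically, making the result deterministic; the
implementation is a two-pass Dijkstra (bottleneck, then total-F within the
allowed set) and is tested against exhaustive enumeration on small grids.

PCA ensembles are pooled across peptides, each frame centred, superposed
onto the pooled mean structure by Kabsch least-squares rotation (proper
rotations only; two align→re-mean iterations), and the covariance of the
flattened CA coordinates diagonalized. Projections keep per-peptide labels
so per-peptide surfaces share a common grid. Eigenvector signs follow a
fixed convention (largest-magnitude entry positive) for reproducibility.

## Numerical and degenerate-input choices

- All distance criteria are inclusive (≤).
- Zipper partition functions are evaluated in log space (log-sum-exp).
- Overlapping beads are finite by construction (soft-core, softened
  Coulomb), so MC never sees a non-finite energy from an overlap; a
  non-finite model energy aborts the run naming the replica and sweep.
- Helicity uses all (O_i, HN_{i+4}) pairs present in the topology; an
  ensemble with no eligible pairs is an error, not a zero.
- Kabsch superposition rejects < 3 points and collinear sets.
- A single-temperature "ladder" is accepted by the sampler (plain MC);
  equal temperatures are allowed so degenerate ladders remain usable.
- Trajectory round trips preserve coordinates to PDB precision (10⁻³ Å)
  and metadata exactly (sidecar parsing uses round-trip float precision).

## What the synthetic models do and do not capture

The CG chain and the zipper model emulate the *structure* of the problem:
a two-strand topology with a 7-bond native registry, two cross-strand
contacts, tunable loop flexibility and contact strengths, and the
folded/unfolded/intermediate bookkeeping applied to real trajectories.
They do not emulate all-atom energetics — no transferable force field, no
implicit-solvent electrostatics, no solvent contribution to entropy — so
agreement of this package's estimators with its own models' closed forms
validates the *machinery* (sampling, counting, estimation, landscapes),
not any all-atom prediction. Literature thermodynamic values appear only
as calibration anchors and worked-example inputs. Known limitations: the
CG folded-population separation between the GB1m3-like and GB1p-like
presets is modest (~0.06 at 270 K with the packaged run sizes); the
zipper GB1m3-like melting temperature is far above the measured one (see
above); and CG sampled profiles along N_HB are unimodal where the real
peptides show two basins.
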