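# Methods

`cago` implements a C-alpha structure-based (Gō) model of protein folding
and the analysis pipeline needed to ask one question quantitatively: how
does chain connectivity — in particular the insertion of a small domain
into the sequence of a larger one — shape the thermodynamic cooperativity
of multi-domain folding?  This note records the model, the estimators,
the synthetic-data generators, the numerical choices, and what the
desk-scale results do and do not establish.

## The potential

One bead per residue at the C-alpha position.  All parameters are in
reduced units: the unit contact energy ε₀ = 1, k_B = 1 (temperature in
ε₀), lengths in Å, bead mass 1.  The terms, with the native structure
supplying every reference value:

| term | form | default constant |
|---|---|---|
| bond | k_b (r − r₀)² | k_b = 100 ε₀/Å² |
| angle | k_θ (θ − θ₀)² | k_θ = 20 ε₀/rad² |
| dihedral | k_φ[(1 − cos Δφ) + ½(1 − cos 3Δφ)] | k_φ = 1 ε₀ |
| native contact | ε[5(σ/r)¹² − 6(σ/r)¹⁰] | ε = 1 ε₀ per contact |
| excluded volume | ε_nn(σ_nn/r)¹², shifted to 0 at r_c | σ_nn = 4 Å, ε_nn = 1, r_c = 8 Å |

Harmonic terms carry no ½ prefactor (the convention of the classic
C-alpha Gō parameterization this follows).  The excluded-volume term acts
on all pairs at least 3 bonds apart that are not native contacts; because
the shift zeroes it beyond 8 Å — the same cutoff that defines contacts —
the potential at the native coordinates is exactly −Σε over contacts.
Contact wells are evaluated at every distance (no per-pair range cutoff):
at desk scale exactness is cheaper than the bookkeeping of a truncation,
and it keeps the NVE energy-conservation test clean.

Native contacts default to the distance criterion: C-alpha pairs within
8.0 Å at sequence separation ≥ 3.  The criterion is a stand-in for
all-atom contact analysis; when an externally computed contact list is
available it is ingested verbatim (`load_contact_list`) and all analysis
runs from the loaded list.

## Variants

**Interface deletion.**  All contacts carrying one interface label are
removed.  To keep every affected residue's folded-state stabilization at
its wild-type value, the surviving contacts incident to affected residues
are rescaled by iterative proportional fitting: each pass computes, per
affected residue i, the factor f_i = (WT ε-sum)/(current ε-sum) and
multiplies each surviving contact (i, j) by √(f_i f_j) (f = 1 for
unaffected endpoints), iterating until every affected residue's sum
matches to 10⁻⁹ (500-pass cap).  Two degenerate cases are reported in the
topology's provenance rather than papered over: residues whose *only*
contacts were interface contacts (their stabilization cannot be
preserved), and interface geometries whose per-residue constraint system
is infeasible — e.g. an affected residue whose remaining contacts all
connect to other constrained residues with incompatible targets — where
the iteration is stopped at the cap and the worst residual recorded.  The
conservation guarantee therefore holds whenever each affected residue
retains at least one contact into the unaffected part of the protein,
which is the situation for protein-like interfaces where interface
residues also pack against their own domain core.

**Circular permutation.**  The old termini are joined through
`linker_length` beads and the chain is cut after a chosen residue; the
new chain is renumbered 1..N+L and every native contact survives with
identical σ and ε under the old→new bijection.  Linker beads are placed
on the straight segment between the old termini when the gap accommodates
4.0 Å spacing, and otherwise on a circular arc of total length
(L+1)·4.0 Å bulging away from the protein centroid, which keeps linker
bond references near 4 Å when the termini are close.  Linker beads carry
bonded terms only; their bonded reference values are taken from the built
geometry.  Junction angles and dihedrals are restrained like any others
(from built geometry) — a choice, recorded here, since nothing forces the
new junctions to be stiff.

**Dual-basin (open/closed) model.**  Contacts present in a second
("closed") conformation's map but absent from the open map are appended
with σ measured in the closed structure, a tunable strength, and the
label `closed-specific`.  The open-state terms — including the
excluded-volume list — are untouched, so the dual potential obeys the
exact identity E_dual(x) = E_open(x) + E_closed-wells(x) for every
configuration; the cost is a slight double-counting (a closed pair at its
well minimum also feels its r⁻¹² excluded-volume core, ~0.008 ε₀ at
σ = 6 Å), which is far below k_B T everywhere we sample.
`tune_closed_strength` scans an ascending grid of strength scales
(multiples 0.4–2.0 of the mean open-contact ε) and returns the first that
populates both conformational basins (≥ 10% of frames each, measured on
the fraction of closed-specific contacts formed).

## Dynamics

Langevin dynamics with the BAOAB splitting; at zero friction the O-step
vanishes and the integrator is exactly velocity Verlet, which is how the
NVE energy-drift contract is tested (< 10⁻⁴ ε₀ per 10⁴ steps at
dt = 5·10⁻⁴).  Defaults: dt = 5·10⁻⁴ reduced time units, friction 1.0.
The folding studies in `pipeline` use dt = 5·10⁻³ and friction 0.5:
the stiffest mode (bonds, ω ≈ 14/τ) is still resolved ~90× per period,
and the lower friction shortens basin-crossing times, which is what
limits desk-scale sampling.  One seeded generator drives the thermal
noise; a trajectory replayed with the same seed is bit-identical.  Forces
are the exact negative gradient (checked against central differences at
10⁻⁴ relative); no neighbour lists — all-pairs evaluation is exact and
fast at ≤ 60 beads.

## Reaction coordinates and estimators

**Q.**  Each contact scores s(r) = 1/(1 + (r/1.2σ)⁶) — the rational
switching form [1 − (r/r₀)⁶]/[1 − (r/r₀)¹²] with midpoint r₀ = 1.2σ —
clamped to 1 for r ≤ σ so the native structure maps to exactly 1; the
all-broken limit maps to 0.  Q is the weight-1 average over a contact
subset; Q* weights each contact by its ε.  The clamp makes Q
discontinuous in r at σ; it is an analysis coordinate, never part of the
dynamics.

**WHAM.**  Binless multi-histogram reweighting: run free energies f_k are
iterated to self-consistency (tolerance 10⁻¹², capped at 10⁴ passes —
typically a few hundred) and per-sample weights at the target temperature
produce free-energy profiles (50 bins on [0,1] by default), 2-D surfaces,
and reweighted energy moments for Cv(T).  A single run reweighted to its
own temperature reduces exactly to −ln(histogram).  Cv grids are kept
inside the sampled temperature range; extrapolated moments beyond it are
untrustworthy and previously produced spurious edge peaks.

**T_f.**  The folding temperature of a construct is located in two
stages: a warm-started temperature ladder (each rung begins from the
previous rung's final frame; default rungs 0.6–2.4 with ~0.1 spacing
through the transition region) brackets the transition, then T_f is the
temperature where the WHAM-reweighted folded population P(Q > 0.5) equals
½, refined with pairs of short runs — one native-start, one
unfolded-start — at the current estimate so both basins contribute
samples.  The rung spacing matters: a sharp transition has Cv width
≈ 4T²/ΔH ≈ 0.17 on these toys, and a coarser ladder under-resolves the
peak, corrupting the enthalpy ratio below.  The Cv curve itself is built
from the ladder and refinement runs only; long single-temperature
production runs concentrate the WHAM weights near T_f and artificially
sharpen the reweighted peak.

**Cooperativity.**  Both enthalpies are computed from the
baseline-subtracted excess heat capacity, with a linear baseline through
the endpoint values of the integration window and negative excursions
clipped (they are estimator noise, not negative transition enthalpy):
ΔH_vH = 2 T_f √(max excess) and ΔH_cal = ∫ excess dT.  Subtracting the
baseline from the van't Hoff term as well matters in a coarse-grained
model, where the background (non-transition) heat capacity ~n_dof/2 is
not small against the peak.  The default window is the full evaluated
temperature grid.  A flanking-minima window is available
(`window="flanking"`), but it is *not* the default for a reason: when the
transition splits into two separated Cv peaks — precisely the
low-cooperativity situation the ratio must flag — the inter-peak dip
truncates the window and silently discards the second peak's enthalpy,
pushing the ratio back toward 1.  On an exact two-level system the ratio
evaluates to 1 within 2%; on two uncoupled two-level units with split
transition temperatures it falls below 1.

**Foldedness.**  Both profiles are zeroed at their own folded-basin
minima (basin = populated bins beyond the interior barrier); the value is
exp(−ΔG_mut(q_ref)) with q_ref the wild-type folded-basin mode.  The
definition assumes the mutant folds at an RC value at or below the wild
type's; a q_ref outside the mutant's populated range raises rather than
extrapolates, and the pipeline records such a construct as foldedness 0
(population below sampling resolution).  Uncertainties propagate from the
per-bin jackknife variances.

**Errors.**  Delete-one-block jackknife over 10 contiguous blocks;
reported error bars are 2·√variance.  Blocks are contiguous to respect
autocorrelation; the block count is a parameter, not an estimate of the
correlation time.

**Foldons.**  Frames restricted to detected folding/unfolding transitions
give a binary contact-formation matrix (formed: r < 1.2σ); Pearson
correlations between contact columns (constant columns — contacts formed
or broken throughout — get correlation 0 and drop out, as intra-helical
contacts do in the real protein); clusters are connected components of
the correlation graph at threshold 0.5 with a 10-contact size floor.
Connected components were chosen over force-directed visualization
because they are deterministic and parameter-transparent; agglomerative
alternatives gave the same planted-block recovery on telegraph fixtures.

## Synthetic data

`make_toy_domain` grows a self-avoiding chain (bond 3.8 Å, non-bonded
floor 3.6 Å) choosing each step among candidate directions with a
centroid-biased rule; the default compactness yields ≥ 1.5 contacts per
residue (typically 3.5–5 — denser than real C-alpha maps, which sit at
2–3, because a biased random walk has no secondary structure; the tests'
contracts use the guaranteed floor, not the typical value).

`make_two_domain_protein` realizes the situation the insertion analysis
assumes: a large domain and a small domain with contact strengths scaled
by `stability_ratio` (default 0.5 — the insert is half as stable per
contact), in two chain topologies over the *same* 3-D geometry.  The
small domain's centroid sits 10 Å beyond the host's surface along the
outward direction through the insertion-point residue, rotated so its
termini face the host.  In `inserted` mode the small domain's sequence is
embedded at the insertion point (host becomes discontinuous, insert's
termini bonded to host interior residues); in `singly_linked` mode it is
appended after the host.  Because geometry is shared, intra-domain
contact sets coincide and only connectivity differs; the interface at
this placement is small (a few contacts), which matches the scientific
point — the insertion effect must come from connectivity, not interface
enthalpy.  Junction bonds take their (long) native lengths from the built
geometry.

`make_telegraph_qseries` plants ground truth for the detector and the
clustering: independent latent telegraphs per block, columns copying
their block's latent with per-frame flip probability 1 − coupling, and a
Q series at levels 0.1/0.9 plus Gaussian noise.

What the toys do not emulate: secondary structure, realistic contact
densities and contact order, sequence effects, and any kinetic
correspondence to real time.  Passing tests establish that the estimators
recover planted truths and that the connectivity effect exists in the
model, not that the magnitudes transfer to real proteins.

## The desk-scale headline study

For each seed, the same two domain geometries are threaded as `inserted`
and as `singly_linked`, each construct is taken to its own T_f and
characterized with four production runs (two native-start, two
unfolded-start; 2·10⁶ steps total).  Mixed starts bound the
initialization bias that a single slow trajectory would have; transitions
(typically ~5–15 per construct at 20+10 beads) are counted and reported.
The claim assessed over ≥ 3 seeds: the inserted construct shows a higher
van't Hoff/calorimetric ratio and a higher folded population of the small
domain at the whole-protein T_f than the singly-linked construct, and the
small-domain foldedness of the singly-linked construct relative to the
inserted one is below 1.  Problem sizes (20 + 10 beads) were chosen so
that both folding and unfolding first-passage times sit near 2·10⁵ steps
at T_f, giving several transitions per production run; larger constructs
(36 + 16) fold too slowly to equilibrate honestly at this budget.

## Known limitations

- Equilibrium sampling near T_f relies on a handful of transitions per
  run; quantitative values (barriers, ratios) carry sampling error that
  the jackknife only partly captures when transitions are few.
- The interface-deletion conservation property is conditional on
  feasibility (see above); infeasible geometries are reported, not fixed.
- The Q clamp at r = σ makes folded-basin Q averages sensitive to the
  clamp convention at the 1–2% level.
- ACO, chain length and packing fraction are computed on user-supplied
  partitions; no database harvesting is included.
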