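# cago — C-alpha Gō models of multi-domain folding cooperativity

`cago` builds coarse-grained structure-based (Gō) models of proteins —
one bead per residue, a potential whose minimum is the native structure —
simulates their folding with Langevin dynamics, and measures how chain
connectivity shapes folding cooperativity.  It is aimed at the
multi-domain situation where a small domain is *inserted* into the
sequence of a larger one (the host becomes discontinuous along the
chain), as in adenylate kinase, where the NMP and LID domains are
inserted into the CORE.

The package covers the full computational experiment around that
question:

- **Model building** (`structure_io`, `sbm`): read C-alpha structures
  from PDB text, compute or load native contact maps, label contacts by
  domain (intra / interface), and build the Gō potential — plus the
  engineered variants: interface-deletion mutants that conserve each
  affected residue's total contact stabilization, circular permutants
  (old termini joined through a linker, new termini cut elsewhere, all
  native contacts preserved under renumbering), and dual-basin models
  with closed-state-specific contacts from a second conformation.
- **Simulation** (`dynamics`): exact forces, BAOAB Langevin integrator
  (velocity Verlet at zero friction), bit-reproducible given a seed.
- **Thermodynamics** (`thermo`): the fraction of native contacts Q via a
  smooth switching function, WHAM reweighting into free-energy profiles
  ΔG(Q) and 2-D surfaces, heat-capacity curves Cv(T), the folding
  temperature T_f, the van't Hoff/calorimetric enthalpy ratio
  ΔH_vH/ΔH_cal (1 = two-state cooperative), "foldedness"
  exp(−ΔG_mut(q_ref)) of a variant relative to the wild type, transition
  detection, and block-jackknife errors.
- **Foldons** (`foldons`): contacts that form and break together across
  folding transitions, found as connected components of the
  contact-formation correlation graph.
- **Domain metrics** (`domain_metrics`): absolute contact order (mean
  sequence separation of contacting pairs), chain length and packing
  fraction per domain, inserted-vs-discontinuous comparisons, and
  functional sites spanning a domain interface.
- **Synthetic data** (`synth`) and the **pipeline** (`pipeline`):
  deterministic toy two-domain proteins in inserted and singly-linked
  topologies over the same 3-D geometry, plus the end-to-end study —
  ladder + refinement to find T_f, mixed-start production runs, and the
  inserted-vs-linked comparison.

The central measurable claim, reproduced on toys at desk scale: with a
less stable small domain (contact strength ratio 0.5), the *inserted*
topology keeps the small domain more folded at the whole-protein T_f
than the *singly-linked* one (about tenfold in population), and shows
the higher ΔH_vH/ΔH_cal cooperativity ratio, because insertion pins the
small domain's termini to the folded host.  The population/foldedness
signature is robust seed to seed; the scalar ratio carries substantial
sampling error at desk scale (see docs/methods.md).

## Worked example

```python
import numpy as np
from cago import (ToyProteinSpec, make_two_domain_protein, build_wt_model,
                  run_langevin, compute_q, detect_transitions)
from cago.pipeline import cooperativity_study

spec = ToyProteinSpec(n_large=20, n_small=10, topology_mode="inserted",
                      insertion_point=10, stability_ratio=0.5, seed=0)
structure, cmap, partition = make_two_domain_protein(spec)
topo = build_wt_model(structure, cmap)

res = cooperativity_study(topo, cmap, partition, seed=2)
print(f"T_f = {res.T_f:.2f}")
print(f"barrier = {res.barrier:.1f} kT")
print(f"dHvH/dHcal = {res.coop_ratio:.2f}")
print(f"transitions observed = {res.n_transitions}")
```

Output:

```
T_f = 1.55
barrier = 4.8 kT
dHvH/dHcal = 0.72
transitions observed = 1
```

Reading: at its folding temperature (1.55 reduced units) the inserted
construct crosses a single ~4.8 k_BT free-energy barrier between the
unfolded and folded basins; the enthalpy ratio of 0.72 sits below the
strict two-state limit of 1, as expected for a two-domain protein whose
small domain is only half as stable as its host; and the production runs
caught one complete folding/unfolding transition (barrier crossings are
rare events at desk scale — error estimates come from the jackknife).
Running the same geometry as a singly-linked chain lowers the small
domain's folded population roughly tenfold — the insertion effect.

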