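# multipatch

A virtual next-generation multineuron patch-clamp (multipatch) rig and the
analysis toolkit that goes with it.  Multipatch experiments record from up
to 10 neurons simultaneously with whole-cell pipettes and probe every
ordered pair for a monosynaptic connection; automated pipette pressure
control and detergent cleaning let failed pipettes retry immediately
("clean-to-complete") and let finished clusters be extended with fresh
cells while others are maintained ("clean-to-extend").  This package
implements the computational side of that workflow for people who plan,
simulate, or analyse such experiments:

- **planner** — connection-count combinatorics and yield simulation.  With
  `n` co-recorded cells the tested directed pairs are `c = n(n-1)`; an
  extension round with `n_new` fresh and `n_old` maintained cells adds
  `c_new = 2·n_new·n_old + n_new(n_new-1)`.
- **rig_geometry** — manipulator-to-microscope registration (Kabsch /
  orthogonal Procrustes without reflections), staging-target planning 200 µm
  above the slice, axis-aligned approach paths and well-wall reachability at
  the 27° approach angle.
- **pressure_rig** — a discrete-event pneumatic controller: LOW (+20 mbar),
  HIGH (+70 mbar), PATCH, ATMOSPHERE and CLEAN channels routed per pipette
  through a three-valve tree; the patching-phase state machine; and the
  30 s cleaning pressure schedule (5 × suction/pressure cycles at
  −350/+1000 mbar plus two 10 s expulsions).
- **synthgen** — seeded synthetic electrophysiology: 20 kHz current-clamp
  sweeps held near −60 mV, 4-AP/20 Hz stimulation slots, double-exponential
  PSPs with trial-to-trial variability, spontaneous EPSP traces, and
  voltage-clamp test pulses with known access/input resistance — all with
  ground truth for testing the analysis chain.
- **ephys** — resting potential, access/input resistance from a
  200 ms/10 mV test pulse, spike detection, AP features by the 10 mV/ms
  threshold rule, rheobase-based stimulus selection and quality control
  (exclude resting potential above −60 mV or access resistance ≥ 40 MΩ).
- **detect** — Clements–Bekkers template-scaling event detection
  (criterion = fitted scale / standard error of the fit) and evoked
  connection calling on sweep-averaged traces.
- **stats** — connection probability, Fisher's exact test, the Wald CI for
  a difference of proportions `(p1−p2) ± z·√(p1(1−p1)/n1 + p2(1−p2)/n2)`,
  and TOST-style relative-difference equivalence reports.
- **io / cli** — an HDF5 sweep container, graph exports (edge CSV,
  adjacency JSON, GraphML), a reproducible end-to-end pipeline and the
  `mpk` command line.

## Worked example

Plan the three-session human-slice experiment — a full 8-pipette cluster,
then two clean-to-extend rounds with (4 new, 4 maintained) and
(5 new, 3 maintained) cells:

```python
>>> from multipatch.planner import SessionPlan, plan_summary
>>> s = plan_summary(SessionPlan(sessions=((8, 0), (4, 4), (5, 3))))
>>> s.total_cells, s.total_tested, s.per_session_tested
(17, 150, [56, 44, 50])
```

17 neurons recorded in total; 56 directed pairs probed in the first
cluster, 44 and 50 more in the extension rounds — 150 probed connections
from one slice.  Cell ids follow the `cell.session` convention
(`'1.1'` … `'9.2'` … `'17.3'`).

Simulate a full screening experiment and recover its connectivity:

```python
>>> from multipatch.synthgen import synth_cluster
>>> from multipatch.detect import screen_connections, build_connectivity
>>> sweeps, truth = synth_cluster(n_cells=8, p_conn=0.15, n_sweeps=40, seed=42)
>>> calls = screen_connections(sweeps)
>>> result = build_connectivity(calls, SessionPlan(((8, 0),), 8),
...                             positions=truth.soma_positions_um)
>>> result.n_connected, result.n_tested, truth.n_edges
(9, 56, 9)
```

The detector finds exactly the 9 planted synapses among the 56 tested
pairs.  The same steps run from the shell:

```sh
mpk synth --cells 8 --p-conn 0.15 --sweeps 40 --seed 42 -o cluster.h5
mpk connect cluster.h5 -o edges.csv
mpk stats compare-probability --found1 38 --tested1 150 --found2 25 --tested2 150
```

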