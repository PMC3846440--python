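# sbmlfuse

Desk-scale SBML model composition and simulation:

- **Match** compartments, species, and reactions of two SBML (Level 2/3)
  documents by MIRIAM annotation and exact effective-name comparison, with
  per-class similarity percentages and optional manual one-to-one pairs.
- **Merge** the two models into a single valid SBML document. Model 1
  pivots: matched elements keep model-1 attributes (every differing
  attribute is warned), unmatched model-2 elements are carried over and
  renamed with a `<model2-id>_` prefix on id collision, global parameters
  are never merged, and namespaces are unioned.
- **Simulate** the composed (or any) model with a built-in kinetic ODE
  engine: content-MathML kinetic laws, stiff-capable adaptive integration
  (LSODA) with configurable tolerances, parameter/initial overrides, flux
  output, experimental-CSV overlay with RMS deviations, and an independent
  fixed-step RK4 reference integrator used as a correctness oracle.
- **Generate** small test-suite-style fixture models from reaction-scheme
  strings (`"S1+S2 -> S3+S4, 2S3+S4 -> S1+S2"`), including 40 predefined
  scheme groups, seeded random model pairs, and the worked-example pair
  `case00015`/`case00020`.

Everything runs offline on plain-text inputs; no model repository or
registry access is required.

## CLI

```sh
# similarity percentages (Dice of exactly matching names per class)
sbmlfuse similarity model1.xml model2.xml --details

# automatic composition; manual pairs via --match pairs.json
sbmlfuse compose model1.xml model2.xml --out composed.xml --report report.json
# report.json carries the ordered warnings and both id maps

# simulate: trajectory CSV, overrides, fluxes, experimental overlay
sbmlfuse simulate composed.xml --out traj.csv --t-end 10 --points 200 \
    --set k1=0.5 --init S1=2 --flux reaction1 --experimental exp.csv

# generate fixture models
sbmlfuse generate --group 21 --seed 1 --out g21.xml
sbmlfuse generate --worked-example --out-dir fixtures/
sbmlfuse generate --pair --seed 7 --out-dir fixtures/

# debugging dump of the internal representation
sbmlfuse dump model.xml
```

Manual match files are JSON with per-class id pairs
(`{"species": [["S1", "S1"]], "compartments": [], "reactions": []}`);
one-to-one use is enforced. `compose` exits 0 on a clean run, 1 when the
composition succeeded with warnings (`--no-warn-exit` suppresses), and 2
on any error (level/version mismatch in strict mode, invalid match table,
unreadable input).

## Library

```python
from sbmlfuse import (
    parse_sbml, write_sbml, build_match_table, compose,
    SimulationSettings, simulate, worked_example_pair,
)

m1, m2 = worked_example_pair()
result = compose(m1, m2, build_match_table(m1, m2))
print([r.id for r in result.composed.reactions])
# ['reaction1', 'reaction2', 'case00020_reaction1', 'case00020_reaction2']
out = simulate(result.composed, SimulationSettings(t_end=5.0))
```

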