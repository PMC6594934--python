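# oxybox

A box model of the coupled marine oxygen and nitrogen cycles, built to
study a counterintuitive consequence of long-term ocean warming: a
warmer ocean holds less dissolved oxygen and grows larger
oxygen-deficient zones, yet its total oxygen inventory can end up
*above* preindustrial.  The reason is the nitrogen cycle.  Where
dissolved O₂ falls below 5 mmol m⁻³, organic matter is respired with
nitrate instead of oxygen (denitrification), and every mole of NO₃
lost this way spares

r<sub>O₂:P</sub> / r<sub>NO₃:P</sub> = 169.6 / 119.68 ≈ 1.42 mol O₂,

so a net loss of fixed nitrogen is an implicit interior oxygen source.
Nitrogen fixation is the mirror-image sink, but it responds with a lag
and cannot act in cold surface waters — deep-water formation in a cold
Southern Ocean is a "loophole" through which nitrate deficits escape
the fixation feedback.  The package is for biogeochemical modellers
who want this mechanism, and the tracer accounting that demonstrates
it, in an analyzable, fast, fully conservative form.

## What's in the box

* **Five-box world ocean** (warm low-latitude surface, cold Southern
  Ocean and northern surfaces, a thermocline/OMZ box, the deep ocean)
  with loop overturning + bilateral mixing, exactly
  inventory-conserving.
* **Ecosystem**: implicit-biomass production with ordinary
  phytoplankton (N- and P-limited) and diazotrophs (P-limited only,
  < ½ the growth rate, nothing below 15 °C); aerobic vs denitrifying
  remineralisation with a capacity-limited sub-box suboxia closure.
* **Idealised tracers**: ideal age, abiotic O₂, preformed PO₄, and
  TOU = 169.6 × regenerated PO₄.
* **Scenario generator**: prescribed multi-millennial warming (+3.1 °C
  volume-weighted peak in year 3380) and an overturning
  dip–recovery–overshoot trajectory; a preindustrial control; a
  compensating-fixation counterfactual.
* **Budget diagnostics**: the oxygen-budget identity
  ΔO₂ = cumulative air–sea flux + 1.417 × (net NO₃ loss), closed to
  < 0.01 Pmol on every run by construction, plus suboxic volume, N*,
  and fixation-lag detection.

See `docs/methods.md` for the model description and design choices.

## Worked example

```python
import oxybox as ox

# oxidant accounting of the remineralisation chemistry
s = ox.StoichiometryParams()
print(s.o2_demand_per_orgN())               # 10.6   mol O2 per mol organic N
print(s.no3_demand_per_orgN())              # 7.48   mol NO3 per mol organic N
print(s.o2_per_no3_lost())                  # 1.4171 mol O2 per mol NO3 lost
print(s.o2_equivalent_of_nitrate_loss(6.2)) # 8.79   Pmol O2 per 6.2 Pmol NO3

# the full experiment
config = ox.ModelConfig()
state, report = ox.spinup(config)           # ~23,000 yr to steady state
forcing = ox.make_warming_scenario(ox.ScenarioParams(), config.geometry)
result = ox.run(config, state, forcing)     # years 1850-8000

f = result.frame
budget = ox.decompose_budget(f, 1850.0, 8000.0, s)
print(budget.delta_o2)                    # +2.10  Pmol: final O2 ABOVE preindustrial
print(f["o2_inventory_pmol"].min()
      - f["o2_inventory_pmol"].iloc[0])   # -9.67  Pmol: transient deoxygenation first
print(-budget.delta_no3)                  # 4.15   Pmol nitrate lost (16% of inventory)
print(budget.nitrate_loss_o2_equivalent)  # +5.88  Pmol O2 from the nitrate loss
print(budget.airsea_flux)                 # -3.78  Pmol net outgassing
print(budget.residual_primary)            # ~5e-12 Pmol: the identity closes
```

The run output is a tidy `pandas.DataFrame` (one row per year) with
global inventories, cumulative fluxes, per-box tracers and rate
series; `ox.report(result)` summarises the sign pattern (O₂ dip then
overshoot, net fixed-N loss, suboxic expansion, fixation lagging
denitrification — here by 90 yr).

## Command line

```bash
oxybox show-config > config.yaml          # all defaults, editable
oxybox spinup --config config.yaml --out state.csv
oxybox simulate --config config.yaml --state state.csv \
       --scenario warming --out run.csv --report report.txt
oxybox budget --run-output run.csv --t0 1850 --t1 8000
```

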