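# Methods

`oxybox` integrates the coupled marine oxygen and nitrogen cycles in a
five-box world ocean to reproduce, at desk scale, a counterintuitive
mechanism of long-term ocean warming: expanding oxygen-deficient waters
shift respiration from oxygen to nitrate (denitrification), and when
nitrogen fixation fails to keep pace the resulting net loss of fixed
nitrogen is an *implicit oxygen source* — after a transitory
deoxygenation the oxygen inventory can end up above its preindustrial
value.

## Model structure

### Boxes and circulation

Five boxes partition the 1.3×10¹⁸ m³ world ocean: a warm low-latitude
surface (LL, 1.8×10¹⁶ m³, 22 °C), a cold Southern Ocean surface (SO,
6×10¹⁵ m³, 4 °C), a cold northern surface (NS, 4×10¹⁵ m³, 6 °C), a
low-latitude thermocline box hosting the oxygen-minimum zone (OMZ,
2.72×10¹⁷ m³, 10 °C) and the deep ocean (10¹⁸ m³, 2 °C).

Advective transport follows fixed closed loops (in Sv): deep water
upwells in the Southern Ocean (Deep→SO 25), where part re-subducts
(SO→Deep 15, an AABW-like path) and part flows equatorward (SO→LL 10);
low-latitude water subducts into the thermocline (LL→OMZ 14), which
upwells back (OMZ→LL 10) or drains to depth (OMZ→Deep 4); a northern
branch closes the loop (LL→NS 6, NS→Deep 6).  Constant bilateral
mixing (2–5 Sv) supplements the loops.  The scenario's overturning
factor scales the advective loops only.  Both operators are built so
that the volume-weighted tracer inventory is conserved to rounding,
and the deep ideal age equilibrates near 1000 yr.

This topology encodes the mechanism's two essential pathways: the OMZ
is ventilated from the warm surface where diazotrophs can act, while
the deep ocean is ventilated mainly through a surface too cold for
nitrogen fixation — the "loophole" through which nitrate deficits
escape the fixation feedback.

### Tracers

Prognostic per-box tracers: O₂, NO₃, PO₄ (all mmol m⁻³), plus three
idealised tracers — ideal age (0 at the surface, +1 yr yr⁻¹ inside),
abiotic O₂ (gas exchange and transport only) and preformed PO₄ (reset
to PO₄ in surface boxes every step, passive elsewhere).  True oxygen
utilisation is diagnosed as TOU = 169.6 × (PO₄ − preformed PO₄);
apparent oxygen utilisation (saturation − O₂) is computed for
comparison only.  Temperature is prescribed per box by the scenario,
not prognostic.

### Stoichiometry and oxidant bookkeeping

Organic matter has fixed molar C:N:P:−O₂ = 112:16:1:169.6.  The source
terms, per mol organic P:

| process                       | O₂      | NO₃          | PO₄ |
|-------------------------------|---------|--------------|-----|
| ordinary production           | +169.6  | −16          | −1  |
| diazotroph production         | +146.93 | 0            | −1  |
| aerobic remineralisation      | −169.6  | +16          | +1  |
| denitrification               | 0       | −103.68      | +1  |
| unremineralised remainder     | 0       | +16          | +1  |

Denitrification draws down 119.68 mol of dissolved NO₃ gross (7.48 per
mol organic N) while the organic nitrogen is returned to the fixed
pool, hence the net −103.68.  The diazotroph O₂ credit is
169.6 − 16×(169.6/119.68): newly fixed nitrogen is charged, at entry,
the oxidant debt that its presence in the fixed-N pool represents —
169.6/119.68 ≈ 1.417 mol O₂ per mol N, exactly the oxygen spared per
mole of NO₃ lost to denitrification.  With these terms two ledgers are
theorems of the model, holding step by step to rounding:

* d(NO₃ inventory)/dt = fixation − denitrification, with fixation =
  16 × diazotroph P-fixation and denitrification = 119.68 × P
  denitrified;
* ΔO₂ inventory − cumulative air–sea flux =
  (169.6/119.68) × net NO₃ inventory loss,

provided no organic matter is left unremineralised (a loud failure is
raised if the unremineralised remainder exceeds 1 % of export; in the
default configuration it is zero).  Charging the debt at entry rather
than resolving explicit nitrification keeps the budget identity exact;
a strictly electron-balanced alternative (organic N leaving as N₂
during denitrification) would give 1.25 rather than 1.417 mol O₂ per
mol NO₃ and breaks the identity against the printed conversion
factors.  Surface photosynthetic O₂ release and its oxidant accounting
are therefore design choices of the bookkeeping, not assertions about
pathway-resolved chemistry.

### Ecosystem

Biomass is implicit: production per surface box is
μ_max × Monod × biomass proxy × box volume, with a per-box scale
factor standing in for light/iron limitation (LL 1.0, SO 0.15,
NS 0.5; the small SO value produces an HNLC surface that leaves most
upwelled nutrients unused — without it the loophole cannot operate).
Ordinary phytoplankton take the Liebig minimum of NO₃ and PO₄ Monod
terms; diazotrophs are PO₄-limited only, grow at most at
μ_max_diaz < ½ μ_max_phy, and not at all below 15 °C (a hard step).
A fraction of production (default 0.9) is exported and remineralised
in interior boxes (LL export: 75 % to the OMZ box, 25 % to Deep;
high-latitude export: all to Deep); the remainder recycles in place.
An optional single-parameter "shallowing" knob can shift low-latitude
export towards the thermocline as the surface warms (default off).

Within a time step, aerobic remineralisation may draw a box's oxygen
down to the 5 mmol m⁻³ suboxic threshold but not past it; excess
demand is denitrified while nitrate lasts, and the denitrified share
of a box's remineralisation is its *sub-box suboxic fraction*.  The
reported suboxic volume is Σ V_i f_i (boxes fully below the threshold
count in full).  This closure resolves partial suboxia that a 5-box
discretisation would otherwise represent as an all-or-nothing switch,
and it gives the spin-up a true fixed point: at equilibrium the OMZ
box sits exactly at the threshold with a steady denitrified fraction
(~0.10), balancing fixation at ~11 Tmol N yr⁻¹ against an equal
denitrification sink.

### Gas exchange

Surface boxes relax towards the oxygen saturation of their current
temperature (Garcia & Gordon 1992 combined fit, Benson–Krause
coefficients, salinity fixed at 35, converted to mmol m⁻³ with a
1.025 kg L⁻¹ density) at a constant piston velocity of 1000 m yr⁻¹.
The atmosphere holds ~100× the oceanic O₂ inventory, so its partial
pressure is fixed.  The identical operator drives the abiotic tracer.

## Scenario

Emissions and climate dynamics are out of scope; the experiment
prescribes their oceanic imprint directly: per-box temperature
anomalies rise along lagged smoothstep curves that all peak in year
3380, scaled so the volume-weighted mean equals +3.1 °C there, then
relax slowly towards 90 % of peak.  The warming pattern (relative
amplitudes LL 2.1, SO 0.7, NS 1.3, OMZ 1.4, Deep 1.0) warms the
low-latitude surface most and the upwelling-buffered Southern Ocean
least, keeping the SO below the 15 °C diazotroph cutoff throughout.
The overturning factor dips to ~0.6 around year 2150, recovers through
~2600, peaks near year 3080 and levels off at 1.1.  Generation is
deterministic; the seed argument exists for interface symmetry.

The control scenario has zero anomalies and unit overturning.

## Numerics

Fixed-step forward Euler, dt = 0.05 yr (a hard upper bound; halving dt
leaves all qualitative outcomes unchanged), with operator splitting in
a fixed order: transport → biology → gas exchange → preformed-PO₄
reset.  All biological drawdowns are capacity-limited within the step
(nutrients, oxygen above threshold) so concentrations stay
non-negative without conservation-breaking clips; any residual clip is
counted and logged.  Spin-up integrates under control forcing until
the largest relative tracer tendency falls below 10⁻⁸ yr⁻¹ (reached
after ~23,000 yr from the built-in first guess; the slowest mode is
the fixation–denitrification balance, e-folding ~2,300 yr).  NaNs
abort with a diagnostic dump.  A full 1850–8000 forced run takes
~20 s on one core; the whole experiment, spin-up included, ~2 min.

## The compensating-fixation counterfactual

The counterfactual asks what the warming response would be if nitrogen
fixation compensated denitrification instantly, with no cold-water
loophole.  It shares the default spin-up; on top of the unchanged
producers, a restoring fixation acts in *every* box (deliberately
unphysical in the interior — it is a thought experiment): wherever
N* = NO₃ − 16·PO₄ drops below its preindustrial value, nitrogen is
fixed and nitrified in place at 2 yr⁻¹ × deficit, debiting local O₂ by
1.417 per mol N — the exact mirror of the denitrification source.  The
debit is capped by available oxygen, which has a physically meaningful
consequence: the suboxic OMZ core cannot be compensated (there is no
oxidant there to receive new fixed N), so roughly half of the default
run's nitrate loss — the standing deficit of the suboxic box itself —
persists even under instantaneous compensation.

The comparison between the default and compensating runs is exact in
interior-source form: each run's ΔO₂ − cumulative flux equals
1.417 × its own nitrate loss to < 0.01 Pmol, so the interior-source
difference equals the nitrate-loss-equivalent difference to machine
accuracy.  The *total* ΔO₂ difference between the runs is larger than
that, because restored nitrogen sustains production and hence TOU
(~17 Pmol higher in the compensated ocean) and the two oceans
equilibrate differently with the atmosphere.  A model that resolves
the nitrogen–production feedback cannot reduce the run difference to
the equivalent term alone; the identity-based decomposition is the
rigorous statement.

## What the experiment does and does not emulate

The prescribed trajectories reproduce the shapes and anchor points of
a multi-millennial business-as-usual experiment (peak warming
magnitude and year, overturning dip/recovery/overshoot); they carry no
interannual variability, seasonal cycle or regional structure.  The
box reduction reproduces signs, orderings and identities — transient
deoxygenation then overshoot, net fixed-N loss with lagged fixation,
suboxic expansion, exact budget closure — but not 3-D inventory
magnitudes (solubility decline, total gain, percentage excess,
volumetric expansion factors), which depend on geography the five
boxes cannot carry.  Passing tests therefore certify the mechanism and
its accounting, not quantitative projections for the real ocean.

## Key parameters

| parameter | default | unit | notes |
|---|---|---|---|
| r_O₂:P aerobic | 169.6 | mol/mol | fixed chemistry |
| r_NO₃:P denitrification | 119.68 | mol/mol | gross acceptor draw |
| suboxic threshold | 5.0 | mmol m⁻³ | pathway switch, ties aerobic |
| μ_max ordinary / diazotroph | 6.0 / 0.4 | yr⁻¹ | implicit-biomass closure |
| k_NO₃ / k_PO₄ | 1.6 / 0.1 | mmol m⁻³ | Monod half-saturations |
| biomass proxy | 0.15 | mmol P m⁻³ | scales all production |
| export fraction | 0.9 | – | rest recycles in place |
| diazotroph cutoff | 15 | °C | hard step |
| piston velocity | 1000 | m yr⁻¹ | both O₂ tracers |
| dt | 0.05 | yr | forward Euler bound |
| spin-up tolerance | 10⁻⁸ | yr⁻¹ | max relative tendency |
| ΔT_ocean / peak year | 3.1 / 3380 | °C / yr | scenario anchors |
| recovery level | 1.1 | – | final overturning factor |

Ecosystem rates, half-saturations, transports, box volumes and the
warming pattern are model design choices tuned once to a realistic
regime (O₂ inventory ≈ 97 Pmol, NO₃ ≈ 26 Pmol, deep age ≈ 1000 yr,
global export ≈ 2 Tmol P yr⁻¹, fixation ≈ 11 Tmol N yr⁻¹); they are
not taken from the source experiment, which does not publish them.

## Known limitations

* No sediments, iron, sulfur chemistry, or variable stoichiometry;
  phosphorus is strictly conserved by construction.
* The oxidant bookkeeping is identity-exact rather than
  pathway-resolved (no explicit NH₄/nitrification step).
* One OMZ box concentrates all pelagic denitrification; its standing
  nitrate deficit is a large share of the global loss, which inflates
  the uncompensatable fraction in the counterfactual relative to a
  3-D ocean.
* Gas exchange ignores wind, sea ice and bubbles; solubility uses a
  fixed salinity.
* The onset-lag diagnostic (threshold crossing at control mean +
  max(2σ, 2 %), sustained 10 yr) is a convention; the lag's sign, not
  its magnitude, is the robust output.
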