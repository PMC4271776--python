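# carrierflux

Kinetic modelling of carrier-mediated amino acid transport in plasma-membrane
vesicles — simulate, fit and scan the continuum between obligatory exchange
(antiport) and facilitated diffusion (uniport).

## The problem

Sodium-independent uptake of serine into placental microvillous membrane
vesicles is attributed to exchanger-type transporters (LAT2/SLC7A8), yet
tracer uptake is routinely observed under *zero-trans* conditions — with
nominally no substrate inside the vesicle to drive exchange. Either the
exchange is not fully obligatory, or an unaccounted internal substrate pool
drives it. Distinguishing these hypotheses from uptake data is a modelling
problem: both mechanisms produce Michaelis–Menten-shaped initial-rate
curves, and the measured apparent parameters confound the intrinsic kinetics
with the mechanism and the internal pool.

`carrierflux` implements a minimal symmetric carrier model that spans both
mechanisms with a single parameter and provides the machinery to interpret
vesicle experiments with it: closed-form initial-rate algebra, ODE
time-course simulation, least-squares fitting, sensitivity scans, and a
synthetic-experiment generator for validating the whole pipeline.

## The model

A carrier X binds one molecule of tracer A or unlabelled substrate B on
either membrane face (equal dissociation constant *K* on both sides) and
translocates loaded at a common rate; the unloaded carrier translocates with
relative mobility *h*. Tracer influx into the vesicle follows

```
d[A]ᵢₙ/dt = 2V ( [A]ₒᵤₜ([B]ᵢₙ + Kh) − [A]ᵢₙ([B]ₒᵤₜ + Kh) ) / D
D = 2·Totₒᵤₜ·Totᵢₙ + K(h+1)(Totₒᵤₜ + Totᵢₙ) + 2hK²,   Tot = [A] + [B]
```

with *V* the maximal rate (µmol l⁻¹ min⁻¹, flux per vesicle volume).
`h = 0` is an obligatory 1:1 exchanger; `h > 0` permits net facilitated
transport to diffusive equilibrium.

Under zero-trans conditions ([A]ᵢₙ(0) = 0) the initial rate reduces exactly
to a Michaelis–Menten law in the total external concentration with

```
Vapp = 2V([B]⁰ᵢₙ + Kh) / (2[B]⁰ᵢₙ + K(h+1))
Kapp = (K(h+1)[B]⁰ᵢₙ + 2hK²) / (2[B]⁰ᵢₙ + K(h+1))
```

so a measured (Vapp, Kapp) pair maps to different intrinsic (V, K) under
each assumed mechanism (h) and internal pool ([B]⁰ᵢₙ); `invert_apparent`
solves that mapping in closed form (Kapp is linear in K for h = 0, quadratic
with a unique positive root for h > 0).

## Worked example

```python
import carrierflux as cf

# A measured apparent pair (Kapp = 87 µmol/l, Vapp = 131 µmol/l/min),
# interpreted under facilitated transport with h = 0.5 and no internal pool:
mm = cf.ApparentMM(Vapp=131.0, Kapp=87.0)
p = cf.invert_apparent(mm, cf.InversionContext(h=0.5, B_in0=0.0))
print(p)
# TransporterParams(V=196.5, K=130.5, h=0.5)

# Trans-stimulation: an outward substrate gradient (5 vs 1, arbitrary
# concentration units) drives a transient tracer overshoot for h > 0:
traj = cf.simulate_to_equilibrium(
    cf.CompartmentState(A_out=1.0, B_out=0.0, A_in=0.0, B_in=5.0),
    cf.TransporterParams(V=1.0, K=0.5, h=0.5))
print(cf.detect_overshoot(traj))
# OvershootSummary(has_overshoot=True, peak_value=3.023..., peak_time=11.28...,
#                  equilibrium_value=0.9999...)
```

The internal tracer peaks at ≈3× the bath level before relaxing to the
diffusive equilibrium (equal to the bath, 1.0) — the diagnostic signature of
a *non*-obligatory carrier. An obligatory exchanger (h = 0) instead rises
monotonically to the initial internal total (5.0).

Closing the loop on synthetic data — generate a noisy three-condition
time-course experiment (external unlabelled serine 0/250/1000 µmol l⁻¹, 10 %
CV, n = 3) from the parameters above and re-fit V with the mechanism fixed:

```python
design = cf.ExperimentDesign.timecourse_default(noise_cv=0.1, n_replicates=3)
data = cf.generate_timecourse_experiment(p, 0.0, design, seed=7)
fit = cf.fit_timecourse(data, fixed={"h": 0.5, "Kapp": 87.0, "B_in0": 0.0},
                        n_starts=3, seed=0)
print(fit.params["V"], fit.objective)
# 192.83... 0.0847...
```

V is recovered within ~2 % of the generating value (196.5); the objective is
the relative normalized SSE over all 24 non-zero data points.

A CLI mirrors the library (`carrierflux simulate | invert-apparent |
fit-initial | fit-timecourse | scan | synth`); see `carrierflux --help`.

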