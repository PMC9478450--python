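# heatpulse

Processing toolkit for heat-pulse sap flow measurements on trees, aimed at
users of low-cost NTC-thermistor heat-pulse loggers (and anyone who wants a
tested, scriptable implementation of the classic heat-pulse estimators).

A heat-pulse device fires a ~2 s pulse through a line heater inserted in the
sapwood and records the temperature response at probes a distance `x_d`
downstream and `x_u` upstream of the heater, at several radial depths.
`heatpulse` turns those raw traces into heat-pulse velocity, sap flux
density and whole-tree sap flow:

* **HRM (Heat Ratio Method)** — `V_h = (k/x) ln(ΔT_d/ΔT_u)`, with the
  generalised form `V_h = 2k ln(ΔT_d/ΔT_u)/(x_d+x_u) + (x_d−x_u)/(2(t−t_0/2))`
  for unequal spacings and a finite pulse; resolves low and reverse flows.
* **Tmax method** — `V_h = sqrt(x_d² − 4k t_m)/t_m` from the downstream
  peak time `t_m`, with the finite-pulse form
  `V_h = sqrt((4k/t_0) ln(1 − t_0/t_m) + x_d²/(t_m(t_m−t_0)))`; resolves
  mid/high flows.
* **DMA (Dual Method Approach)** — per measurement, the Péclet number
  `β = ln(ΔT_d,max/ΔT_u,max)` selects HRM when `β ≤ 1` and Tmax otherwise.
* **Flux conversion** — wound correction `V_c = B·V_h`, sap flux density
  `SFD = (ρ_b/ρ_s)(m_c + c_dw/c_s)·V_c`, and whole-tree flow
  `F = Σ_j π(r_j² − r_{j−1}²)·SFD_j` over the sapwood annulus of each
  sensor depth.

The package also contains a forward model of the whole measurement — the
conduction–convection line-source solution
`ΔT(x,t) = q/(4πkt)·exp(−(x−vt)²/(4kt))`, finite pulses by superposition,
sensor noise and ADC quantisation — which doubles as a synthetic-data
generator and as the oracle for the test suite, and a robust reader for the
logger CSV format (corrupted SD-card rows are skipped and counted, truncated
cycles flagged). Thermistor channels stored as raw divider voltages are
converted through the Steinhart–Hart equation.

## Worked example

Simulate four measurement cycles at a true heat-pulse velocity of
36 cm hr⁻¹ (0.01 cm s⁻¹) with realistic sensor noise, then process them
with the shipped example configuration:

```sh
heatpulse simulate --v-h 36 --n-cycles 4 --seed 7 -o field.csv
heatpulse process -i field.csv -c config.example.yaml -o results.csv
```

`results.csv` begins:

```
cycle_id,timestamp,depth_cm,beta,method,v_h_cm_hr,v_c_cm_hr,sfd_g_cm2_s,F_g_s,qc_flags
0,2021-06-01T00:00:00.000Z,0.5,1.99086,Tmax,35.3499,35.3499,0.00631717,0.178768,
0,2021-06-01T00:00:00.000Z,1.5,1.99773,Tmax,34.2491,34.2491,0.00612045,0.178768,
0,2021-06-01T00:00:00.000Z,2.5,1.979,Tmax,38.9274,38.9274,0.00695648,0.178768,
1,2021-06-01T00:30:00.000Z,0.5,1.96966,Tmax,37.4314,37.4314,0.00668915,0.193615,
```

Reading row one: at 0.5 cm depth the Péclet number β ≈ 1.99 exceeded 1, so
the DMA selected the Tmax estimator, which recovered 35.3 cm hr⁻¹ against
the true 36 (the scatter between depths is the imposed 0.01 K sensor
noise acting on the peak time). With the example wood properties
(ρ_b = 0.5 g cm⁻³, m_c = 1.0, c_dw = 1.2 J g⁻¹ K⁻¹) the conversion factor
to sap flux density is 0.6433, giving SFD ≈ 6.3×10⁻³ g cm⁻² s⁻¹, and the
annulus-weighted sum over the three depths yields a whole-tree flow of
0.179 g s⁻¹ for the cycle. `v_c` equals `v_h` because the example config
leaves the wound coefficient at B = 1 (no correction), which the tool warns
about loudly.

The same chain is available as a library:

```python
import heatpulse as hp

geometry = hp.ProbeGeometry(x_d=0.5, x_u=0.5, depths=(0.5,))
medium = hp.MediumParams(k=2.5e-3, v_h=36.0, t0=2.0)
record = hp.generate_pulse_record(geometry, medium, hp.NOISELESS)
summary = hp.summarize_pulse(record)[0]
estimate = hp.dma_select(summary, geometry, k=2.5e-3, t0=2.0)
print(estimate.method_selected, round(estimate.v_h, 2))  # Tmax 35.9
```

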