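# monpool

Reconstruction of the recruitment and firing behaviour of a **complete
motoneuron (MN) pool** from the small sample of MN spike trains that
high-density EMG (HDEMG) decomposition can identify, plus a synchronized
whole-muscle force trace.

HDEMG decomposition typically yields 10–40 motor units out of pools of
several hundred, with a strong bias towards large, high-threshold units.
`monpool` infers what the *rest* of the pool is doing: it maps the
identified units into the full pool, estimates the common synaptic current,
calibrates one leaky integrate-and-fire (LIF) model per identified unit, and
then simulates the entire pool — producing every unit's spike train, the
effective neural drive to the muscle, and (through a motor-unit Hill-type
stage) the muscle force.

## The model

The workflow has four steps.

1. **Mapping.** Motor-unit force recruitment thresholds in a pool of `N`
   units follow a linear-exponential distribution
   `F^th(j) = k1·(k2·j/N + Δ_F^((j/N)^k3))` (for the human tibialis
   anterior: `k1 = 0.50 %MVC`, `k2 = 58.12`, `k3 = 1.83`, fold range
   `Δ_F = 120`). Each identified unit *i*, with recorded threshold
   `F_i^th`, is assigned the pool location `N_i` solving
   `F^th(N_i) = F_i^th`.

2. **Common current input.** The cumulative spike train (CST) of the
   identified units, low-passed to [0; 10] Hz, estimates the common synaptic
   input (CSI); coherence between complementary half-samples checks whether
   the sample is representative enough for this linearity argument. The CSI
   is scaled to a physical current `I(t) = I^th_{N1} + G·(CSI(t) −
   CSI(ft¹_{N1}))`, anchored at the first discharges of the lowest- and
   highest-threshold identified units through the pool rheobase distribution
   `I^th(j) = 3.9 nA · 9.1^((j/N)^1.18)`.

3. **LIF calibration.** Each unit is a single-compartment LIF neuron whose
   parameters all derive from its membrane surface area `S`:
   `R = k_R/S^2.43`, `C = C_m·S`, `τ = RC`, `I^th = ΔV_th/R`
   (`ΔV_th = 27 mV`, `C_m = 1.3 μF/cm²`), plus an inert period `IP` that
   caps the firing rate at `1/IP`. `IP_i` is read off each saturating unit's
   discharge-rate trendline; `S_i` is calibrated by matching simulated to
   experimental smoothed discharge rates. Power-law fits across the
   calibrated units give pool-wide distributions `IP(j) = a·j^b` and
   `S(j) = S_min·Δ_S^((j/N)^c)`, and the derecruitment phase gets apparent
   parameters `R^d = R/k^dth` and `C_m^d` fitted on the down-ramp.

4. **Pool simulation.** `N` LIF models scaled by `S(j)` and `IP(j)` receive
   `I(t)` and predict every unit's spike train. The effective neural drive
   `eND_N` (the [0; 4] Hz low-passed CST of all `N` units) is validated
   against the normalized force trace, and the spike trains can drive `N`
   in-parallel Hill-type motor units to predict muscle force.

Because the source datasets have no machine-readable accessions, the package
ships a first-class synthetic generator (`monpool.fixtures`) that emulates
them: a ground-truth pool with size-principle-ordered properties, a
trapezoidal contraction with physiological common-drive fluctuation, and a
threshold-biased identified subsample.

## Worked example

Reconstruct a 400-unit tibialis anterior pool from a synthetic 32-unit
sample emulating a trapezoidal contraction to 35 %MVC:

```python
from monpool import fixtures as fx
from monpool.model import MotoneuronPool

spec = fx.make_reference_fixture("DTA35-like", master_seed=1)
dataset, info = fx.make_dataset(spec)

results = MotoneuronPool(dataset).fit()
print(results.summary())
pool = results.simulate_pool(seed=101)
print(f"eND_N vs force: r2 = {pool.metrics.r2:.2f}, nRMSE = {pool.metrics.nrmse:.1f}%")
```

prints

```
Motoneuron pool reconstruction
==============================================================
Muscle: TA    pool size N: 400    identified N_r: 32
Identified locations N_i: 96-316
Threshold distribution F^th(j): k1=0.506 %MVC, k2=57.62, k3=1.86, delta_F=120
Coherence (half-sample 0.58 -> full 0.73); CSC vs force r2=0.79, nRMSE=15.1% -> representative
Current input: onset 3.57 s, anchors [5.9, 20.8] nA, gain 5.96e-08 A/unit
IP(j) = 0.0291 * j^0.134 s (22/32 saturating; max rate of MN 1: 34.3 Hz)
S(j) = 1.62e-07 * 2.4^((j/400)^1.8) m^2
Derecruitment: k_th = 0.951, C_m^d = 2.30 uF/cm^2
--------------------------------------------------------------
Per-unit calibration (FIDF agreement on [t_tr0, t_tr3]):
  median nRMSE 7.1%  median r2 0.97  |dft1|<250 ms: 69%

eND_N vs force: r2 = 0.94, nRMSE = 8.0%
```

The identified sample alone (`eND_Nr`) tracks the same force trace with only
r² = 0.79 and nRMSE = 15.1%: reconstructing the missing units roughly halves
the drive-estimation error, because the biased sample misses the small,
early-recruited units entirely.

A command-line interface mirrors the library
(`monpool fixture | map | drive | calibrate | simulate | validate | run-all`);
`monpool run-all --help` shows the end-to-end entry point.

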