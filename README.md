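# helipause

Sequence-dependent DNA unwinding by a processive helicase, simulated and
analyzed end to end: nearest-neighbor duplex energetics, stochastic
multi-base-pair stepping models, single-molecule trace analysis (step and
pause detection, dwell histograms), reduced-χ² kinetic model selection,
n-step single-turnover ensemble kinetics, and the nucleotide-analog
competition model of mechano-chemical coupling.

## The scientific problem

A helicase such as *E. coli* RecQ unwinds duplex DNA against a
sequence-dependent thermodynamic barrier.  In magnetic-tweezers hairpin
assays the enzyme pauses repeatedly at GC-rich positions; in quenched-flow
assays the unwinding time course of forked duplexes depends on their GC
content.  Both observations are explained by a kinetic step size n > 1: the
enzyme melts base pairs one ATP at a time but releases the nascent ssDNA in
~n = 5 bp bursts, so the rate-limiting pause before each mechanical step
depends on the opening free energies of the n base pairs ahead.

Two microscopic models for the pause at kinetic step i are distinguished:

* **simultaneous melting** — all n base pairs open in one activated event,

  τ_p(i) = A · exp( Σ_{s=1..n} G_1bp((i−1)n + s) )

* **delayed release** — base pairs open sequentially, ssDNA is released
  after n bp,

  τ_p(i) = Σ_{s=1..n} A · exp( G_1bp((i−1)n + s) )

with G_1bp the per-base-pair melting free energy (kBT) from the unified
nearest-neighbor parameter set with a monovalent-salt correction, and the
pre-factor A calibrated so that the mean unwinding rate matches the
measured reference (46 nt/s).  The two models differ sharply in pause-depth
contrast and in salt sensitivity, which is what the analysis modules test.

Mechano-chemistry is probed by competing ATP against slowly-released ATPγS
at fixed total concentration: each of the m binding events per n-bp step is
the analog with probability P = [ATPγS]/(k_r·[ATP] + [ATPγS]), inserting
Binomial(m, P) long pauses of mean 1/k_off.  Globally fitting the mean
pause τ = mP/k_off + 1/k_step and rate v = n/τ across analog fractions
yields the coupling ratio C = m/n (bp per ATP) and the on-rate ratio
k_r = k_ATP/k_ATPγS.

The package is aimed at single-molecule biophysicists and enzyme
kineticists who want a tested, fully synthetic (no external data)
implementation of this analysis chain — for method development, power
analysis of experimental designs, and teaching.

## Worked example

```python
from helipause import (make_hairpin, compute_bp_energies, SimulationConfig,
                       calibrate_prefactor, simulate_trajectory)

hp = make_hairpin(seed=1)                 # 174-bp stem, GC clusters at 55/90/120
profile = compute_bp_energies(hp)         # per-bp opening cost, kBT
config = calibrate_prefactor(hp, SimulationConfig(model="delayed", n=5), profile)
print(f"Calibrated pre-factor A = {config.prefactor_s:.3e} s")
traj = simulate_trajectory(hp, config, profile, seed=0)
print(f"Unwound {traj.event_positions[-1]:.0f} bp in {traj.total_time:.2f} s "
      f"(mean rate {traj.mean_rate:.1f} bp/s)")
```

```
Calibrated pre-factor A = 8.093e-04 s
Unwound 174 bp in 4.04 s (mean rate 43.1 bp/s)
```

The pre-factor is the Boltzmann prefactor that scales every pause so the
*expected* mean rate is 46 bp/s; an individual trajectory (here 43.1 bp/s)
scatters around it because pause durations are exponential draws.

Fitting a synthetic mechano-chemical coupling dataset:

```python
from helipause.mechchem import CouplingModel, CouplingParams, make_coupling_dataset

data = make_coupling_dataset(CouplingParams(), noise_frac=0.05, seed=1)
print(CouplingModel(data, n=5).fit().summary())
```

```
Mechano-chemical coupling fit
==============================================
observations (tau, v pairs): 6
kinetic step size n (fixed): 5 bp
k_off (fixed): 2.408 1/s
----------------------------------------------
C = m/n             1.037 +/- 0.116 bp/ATP   (m rounded: 5)
k_ATP/k_ATPgS       1.380 +/- 0.238
k_step              8.445 +/- 0.561 1/s
reduced chi2        0.452
hydrolysis negligible: True
```

The recovered coupling ratio (~1 bp per ATP) and on-rate ratio sit within
their standard errors of the generating values (1.0 and 1.2): one ATP is
hydrolyzed per base pair even though the mechanical step is 5 bp.

A command-line interface mirrors the library:

```bash
helipause synth --out hp.fasta --seed 1
helipause simulate --substrate hp.fasta --n-traces 10 --outdir traces/
helipause stepfind --trace traces/trace_000.tsv --algo ttest --out segments.tsv
helipause analyze chi2scan --substrate hp.fasta --out scan.tsv
```

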