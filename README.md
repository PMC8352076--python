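# kinenet

Group elastic net lifetime-density analysis of multiwavelength first-order
kinetic data.

## The problem

Time-resolved spectroscopy of complex photoinduced processes — photocycles
of retinal proteins, chromophore relaxation cascades, flash photolysis —
produces a signal matrix S(t, w) over a wide logarithmic time window and a
set of wavelengths. If the chemistry is a network of first-order reactions
(dc/dt = K c), the signal is a sum of exponentials shared across
wavelengths,

    S(t, w) = Σ_i D_i(w) · exp(−t / τ_i),

with macroscopic time constants τ_i (eigenvalues of K) and decay-associated
difference spectra (DADS) D_i(w). Classical global multiexponential fitting
requires knowing the number of components, good starting values, and luck
with local minima. `kinenet` instead expands every kinetic trace on a dense
log-spaced grid of time constants and solves a **group elastic net**: for
data vectors b_k and design matrices A_k (A_ij = e^{−t_i/τ_j}, optionally
IRF-convolved),

    min_X  ½ Σ_k ‖b_k − A_k x_{*,k}‖² + λ [ ω/2 Σ_k ‖x_{*,k}‖² + (1−ω) Σ_j ‖x_{j,*}‖ ],

where rows of X are grid time constants and columns are wavelengths. The
group penalty makes whole rows jointly zero or nonzero (one set of time
constants for the entire spectrum); ω tunes the solution continuously from
a few discrete exponentials (ω → 0) to a smooth lifetime distribution
(ω → 1). The two hyperparameters are selected automatically by Bayesian
optimization over cross-validation scores — classical 10-fold CV, or a
restricted leave-n_v-out CV that fixes the support with the penalized fit
and validates with unpenalized least squares on the restricted design. A
sparse solution is discretized into components (with a 5% amplitude
filter) and polished by an unpenalized variable-projection multiexponential
fit; a dense solution is itself the result and flags that the kinetics are
not a small set of first-order decays. See `docs/methods.md` for the full
treatment.

The package is aimed at experimentalists analyzing flash-photolysis,
transient-absorption, or time-resolved fluorescence data, and at method
developers who need a fully synthetic, seeded test bed (reaction networks,
distributed Arrhenius kinetics, Erlang-type and second-order signals,
structured photon noise) for lifetime-density methods.

## Worked example

Recover two decay components from a noisy synthetic trace:

```python
import numpy as np
import kinenet as kn
from kinenet.model_selection import CVSpec

t = np.geomspace(0.05, 50, 35)
signal = (np.exp(-t / 0.5) + 0.7 * np.exp(-t / 10.0))[:, None]
data = kn.KineticDataset(t, np.array([500.0]), signal)

result = kn.algorithm2(data, cv=CVSpec(kind="rcv", reps=60),
                       budgets=(20, 8, 8), seed=5)
print("branch:", result.branch)
for f in result.refined.features:
    print(f"tau = {f.tau:.4g}   amplitude = {f.dads[0]:.4g}")
```

Output:

```
branch: sparse
tau = 0.5   amplitude = 1
tau = 10   amplitude = 0.7
```

The run selects (λ, ω) by restricted CV, takes the sparse branch, and the
refined time constants and amplitudes reproduce the generating values
(0.5 and 10 time units; amplitudes 1 and 0.7). On the ten-component
photocycle-like benchmark (`kn.photocycle_fixture`, σ_rel = 1e-7, eight
synthetic spectra) the same pipeline returns seven features above the 5%
amplitude filter, with refined time constants within a few hundredths of a
decade of the truth.

The estimator itself is scikit-learn-style if you want the pieces
separately:

```python
est = kn.GroupElasticNet(lam=0.05, omega=1e-6).fit(A, B)  # A: (m,n), B: (m,p)
est.coef_          # (n, p) amplitude matrix, rows exactly sparse
```

A thin CLI wraps the library: `kinenet simulate ...`, `kinenet select ...`,
`kinenet discretize ...`, `kinenet fit ...`, `kinenet run ...` (see
`kinenet --help`).

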