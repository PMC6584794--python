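# puffs

Estimate the mass of total particulate matter (TPM) and nicotine delivered to
the mouth of an e-cigarette user, from the user's puffing topography and an
empirical, product-specific emissions model.

## Who this is for

Tobacco-regulatory-science and exposure-assessment researchers who have
(a) machine-puffed emissions measurements for a device/e-liquid pairing and
(b) puffing-topography records — puff flow rate and duration over a use
session — from laboratory or natural-environment monitoring, and who want
per-person, per-session yield estimates rather than machine-regimen yields.

## The model

Emissions are separated into a TPM concentration and a constituent mass
ratio, each an empirical function of the user-behaviour variables puff flow
rate *q* [mL/s] and puff duration *d* [s]:

```
ln Ĉ_TPM(q, d) = b₁ + b₂ ln q + b₃ d + b₄ (ln q)² + b₅ ln(d/1000) + b₆ (q·d)
f̂_NIC(q)      = β₁ + β₂ q
```

Both are fit by ordinary least squares (ln Ĉ on the six-term design row; f on
[1, q]) with full diagnostics (SEs, t statistics, p values, R², adjusted R²,
RMSE). A use session of N puffs with volumes vₙ = qₙ·dₙ then yields

```
Ŷ_TPM = Σₙ Ĉ(qₙ, dₙ)·vₙ        [mg]
Ŷ_NIC = Σₙ f̂(qₙ)·Ĉ(qₙ, dₙ)·vₙ  [mg]
```

The package ships a reference coefficient set for one pen-style e-cigarette
with a tobacco-flavoured 1.8%-nicotine 50:50 PG/VG e-liquid; those numbers
are specific to that pairing and must be refit for any other product
(`puffs fit`). Model agreement is assessed against repeated "playback"
measurements via the through-origin slope *m*, Pearson's *r* and R².

The estimators (`TpmConcentrationModel`, `NicotineMassRatioModel`) follow the
scikit-learn fit/predict protocol and compose with sklearn tooling; the rest
of the package covers topography ingestion and puff detection, session-yield
prediction, agreement statistics, and seeded synthetic-data generators for
the full pipeline.

## Worked example

```python
import numpy as np
from puffs import load_reference_model, predict_session_yield, session_summary
from puffs.synthetic import session_spec_from_targets, simulate_session

tpm, nic = load_reference_model()
print(f"C_TPM(q=30.4 mL/s, d=2.3 s) = {tpm.predict_one(30.4, 2.3):.4f} mg/mL")
print(f"f_NIC(q=30.4 mL/s)         = {nic.predict_one(30.4):.6f} mg/mg")

spec = session_spec_from_targets(mean_duration=2.3, mean_flow=30.4,
                                 total_volume=605.0, session_id="demo")
session, trace = simulate_session(spec, seed=1)
d, q, v, n = session_summary(session)
print(f"session: {n} puffs, mean d={d:.2f} s, mean q={q:.1f} mL/s, volume={v:.0f} mL")
sy = predict_session_yield(session, tpm, nic)
print(f"predicted yield: Y_TPM = {sy.y_tpm:.2f} mg, Y_NIC = {sy.y_nic:.3f} mg")
```

prints

```
C_TPM(q=30.4 mL/s, d=2.3 s) = 0.0166 mg/mL
f_NIC(q=30.4 mL/s)         = 0.009657 mg/mg
session: 9 puffs, mean d=2.64 s, mean q=28.3 mL/s, volume=667 mL
predicted yield: Y_TPM = 17.09 mg, Y_NIC = 0.165 mg
```

Reading: a moderate-intensity session drawing 667 mL of aerosol delivers an
estimated 17 mg of particulate matter to the mouth, of which about 0.17 mg
(≈1%, the mass ratio) is nicotine. The two orders of magnitude between the
TPM and nicotine yields follow directly from f̂ ≈ 0.01 mg/mg.

The same flow is available from the shell:

```sh
puffs detect trace.csv -o puffs.csv                # trace -> discrete puffs
puffs fit --trials trials.csv --model-out m.json   # fit models to trial table
puffs predict --session trace.csv -o yield.json    # per-session yield
puffs validate --model m.json --sessions dir/ --observed obs.csv
puffs simulate design|emissions|session|observed   # synthetic inputs
```

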