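# camvitals

Contactless estimation of four vital signs — pulse rate (PR), respiratory
rate (RR), percutaneous arterial oxygen saturation (SpO2) and tissue
oxygen saturation (StO2) — from RGB video of skin.

Ordinary camera-based photoplethysmography reads pulse from raw color
channels. `camvitals` instead inverts each frame into physical skin
chromophore concentrations — melanin `Cm`, oxygenated hemoglobin `CHbO`
and deoxygenated hemoglobin `CHbR` — which is what makes *both*
oxygen-saturation quantities accessible from one sensor, alongside the
rates. The package is for researchers building or validating camera-based
vital-sign monitors: it contains the full model chain, a ground-truthed
synthetic data generator, and the method-comparison statistics used to
validate against reference devices.

## The model chain

1. **Camera → XYZ.** Device RGB is linear; a 3×4 affine matrix **M1**
   maps (1, R, G, B) → CIE XYZ. M1 is fitted by least squares on a
   24-patch color checker with known XYZ references.
2. **XYZ → concentrations.** A Monte Carlo model of light transport in
   two-layer skin (melanotic epidermis over a hemoglobin-bearing dermis)
   generates 300 diffuse reflectance spectra (400–700 nm, 10 nm steps)
   over physiological ranges of (Cm, CHbO, CHbR), each converted to XYZ.
   A second-order multiple regression per chromophore on
   (1, X, Y, Z, X², Y², Z², XY, XZ, YZ) — the 10×3 matrix **M2** — then
   inverts camera XYZ into concentration maps without further simulation.
   Derived quantities: CHbT = CHbO + CHbR and
   StO2 % = 100·CHbO/CHbT.
3. **Concentrations → vitals.** The ROI-mean hemoglobin time series is
   FIR band-pass filtered into a cardiac band (0.75–3 Hz ⇔ 45–180 bpm)
   and a respiratory band (0.05–0.5 Hz ⇔ 3–30 rpm). PR and RR are
   60 / median inter-peak interval of the filtered CHbT in each band.
   Per beat, the pulse-amplitude ratio φ = PA_HbO/PA_HbR feeds an
   empirical exponential calibration SpO2(φ) = A·exp(−φ/B) + C; StO2 is
   the windowed mean of the raw concentration maps.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Train the inversion, render a ground-truthed synthetic video, and run the
pipeline end to end:

```python
from camvitals import colorimetry as cm, pipeline as pl, synthetic as syn
from camvitals.forward_model import build_training_set
from camvitals.inverse_mapping import fit_m2

training = build_training_set(n=60, photons=3000, seed=7)  # small demo budget
m2 = fit_m2(training, order=2)
print({k: round(v, 3) for k, v in m2.r_squared.items()})

scenario = syn.Scenario(duration_s=120.0, hypoxia_onset_s=None)  # 72 bpm, 15 rpm
run = syn.generate_scenario_series(scenario, seed=5)
video = syn.render_video(run, frame_shape=(48, 48), seed=3)
m1 = cm.fit_m1(video.checker)

config = pl.PipelineConfig(respiratory_taps=301, rr_window_s=30.0, rr_step_s=5.0)
result = pl.run_pipeline(
    pl.VideoSource.from_array(video.frames, fs=scenario.fs),
    m1, m2, config=config, diffuser_frame=video.diffuser,
)
print(result["vitals"][["window_start", "PR", "RR", "StO2", "phi"]]
      .iloc[40:44].round(2).to_string(index=False))
```

Output:

```
{'Cm': 0.982, 'CHbO': 0.96, 'CHbR': 0.94}
 window_start    PR    RR  StO2  phi
         40.0 72.46 15.18 90.73 6.61
         41.0 72.40 15.18 90.73 6.03
         42.0 72.46 15.18 90.73 5.84
         43.0 72.34 15.15 90.73 5.84
```

The R² line is the in-sample fit quality of the demo-sized M2 per
chromophore. Each vitals row is one 20 s analysis window: PR recovers the
scenario's 72 bpm to within a fraction of a beat, RR its 15 rpm, and StO2
sits near the scenario's 88 % tissue saturation (the ~2-point offset is
the known edge bias of the small demo regression). φ is the measured
pulse-amplitude ratio; its absolute scale is meaningful only through an
SpO2 calibration fitted on measured φ (`camvitals.ppg.fit_spo2_calibration`).

The same steps are available from the shell:

```sh
camvitals simulate-spectra --seed 1 --photons 10000 --out work/
camvitals train-m2 --training work/training.csv --order 2 --out work/m2.json
camvitals simulate --seed 1 --duration 540 --out work/video/
camvitals fit-m1 --checker work/video/checker.csv --out work/m1.json
camvitals run --video work/video/frames --diffuser work/video/diffuser.png \
    --m1 work/m1.json --m2 work/m2.json --out work/vitals.csv
camvitals evaluate --est work/vitals.csv --ref work/video/truth.csv --vital PR --out work/pr_report.json
```

`camvitals evaluate` reports Bland–Altman bias, precision (SD of
differences), limits of agreement (bias ± 2 SD), RMSE and Pearson r.

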