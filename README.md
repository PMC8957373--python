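# oxymosaic

Imaging skin hemoglobin oxygen saturation (SO2) with a snapshot
filter-mosaic multispectral camera, using a shallow neural network
trained against a point-probe reference.

Snapshot multispectral cameras put a repeating 4×4 mosaic of 16
interference filters directly on the sensor, capturing a whole spectral
data cube per exposure — fast enough to follow microcirculatory
dynamics, but with broad, overlapping, sensor-specific passbands that
make physics-based inversion (sensor calibration + photon-transport
modelling) difficult. `oxymosaic` implements the data-driven
alternative: during arterial and venous occlusion provocations of the
forearm — which sweep tissue SO2 over nearly the full 0–100% range — a
validated fiber-probe reference records SO2 at 1 Hz, and a 16→3→1 tanh
network is trained on the camera's own mean-normalized spectra to
predict it. The trained network then maps every pixel of a preprocessed
cube to SO2 in milliseconds.

The package covers the full chain:

| module | role |
|---|---|
| `oxymosaic.mosaic` | raw mosaic frames → dark correction, weighted-bilinear demosaicing, 4×4 binning, white normalization |
| `oxymosaic.sampling` | reflectance cubes → mean-normalized 16-channel spectra (random ROI pixels, ROI means, arm masking, reference pairing) |
| `oxymosaic.weighting` | inverse-frequency error weights over 10% SO2 bins |
| `oxymosaic.ann` | `ShallowANNRegressor`: Levenberg–Marquardt training with weighted MSE and validation early stopping (scikit-learn estimator API); `predict_map` for pixelwise SO2 images |
| `oxymosaic.evaluation` | weighted RMS error E_rms,W, leave-one-subject-out harness, hidden-layer sweep, phase statistics, Bland–Altman agreement, venous-only ablation |
| `oxymosaic.synthetic` | a forward-modelled occlusion cohort (optics, sensor, protocol, noise) so the whole pipeline runs without measured data |

The performance metric is the weighted RMS error

    E_rms,W = sqrt( Σᵢ wᵢ (SO2,ref,i − SO2,net,i)² / Σᵢ wᵢ )

with wᵢ the inverse-frequency weight of sample i's 10% SO2 bin, so the
sparsely visited extremes near 0% and 100% count as much as the
mid-range bulk. Method agreement with the reference is summarized per
protocol phase (baseline, end of occlusion, early reperfusion) as
Bland–Altman bias ± 1.96 SD limits.

## Worked example

Simulate the default 20-subject cohort (100 cubes per provocation and
subject, 1% sensor noise, 5%-RMS reference noise, 3% probe-site
mismatch), run the full leave-one-subject-out analysis with the 3-node
weighted network, and summarize agreement per protocol phase:

```python
from oxymosaic.synthetic import simulate_cohort
from oxymosaic.weighting import compute_weight_vector
from oxymosaic.evaluation import (loso_run, cohort_phase_table,
                                  cohort_bland_altman, summarize_phases)

cohort = simulate_cohort(n_subjects=20, seed=1)
weights = compute_weight_vector(cohort.spectra.y)
result = loso_run(cohort.spectra, weight_vector=weights, n_hidden=3, seed=1)
print(f"mean evaluation E_rms,W over {len(result.folds)} folds: "
      f"{result.mean_erms_eval:.2f}%")

table = cohort_phase_table(result.models, cohort.spectra, cohort.traces,
                           cohort.profile.protocol)
print(summarize_phases(table).round(1).to_string(index=False))
for phase, ba in cohort_bland_altman(table).items():
    print(f"{phase:>13}: bias {ba.bias:+.2f}%  "
          f"limits [{ba.lower:+.2f}, {ba.upper:+.2f}]")
```

Output (a few minutes on one CPU):

```
mean evaluation E_rms,W over 20 folds: 8.11%
        phase    source  mean  std  max  min
     baseline    method  57.3  7.7 75.7 43.7
     baseline reference  58.0  7.3 77.5 45.4
end_occlusion    method   6.1  3.2 13.5  0.2
end_occlusion reference   2.0  3.4  8.5 -3.1
      release    method  82.0  5.2 93.7 72.3
      release reference  78.6  6.0 90.5 64.3
     baseline: bias -0.74%  limits [-9.75, +8.28]
end_occlusion: bias +4.09%  limits [-5.85, +14.04]
      release: bias +3.39%  limits [-6.34, +13.13]
```

Reading the numbers: each left-out subject's network disagrees with the
noisy reference by ≈8% weighted RMS — close to the irreducible floor set
by the 5%-RMS reference noise plus the 3% probe-vs-ROI site offset. The
phase table shows the expected behavior at the range edge: at end of
occlusion (true SO2 a few %) the network reads slightly high (6.1% vs
2.0%), because a regressor trained against a noisy target cannot chase
values below the range it has seen — a classic floor effect of
regression at the range edge. Baseline and reperfusion agree with little bias.

A command-line interface wraps the same functionality:

```
oxymosaic simulate --subjects 20 --seed 1 --out-dir cohort/
oxymosaic train cohort/spectra.csv --hidden 3 --out model.json
oxymosaic evaluate cohort/spectra.csv --hidden 3 --out-dir report/
```

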