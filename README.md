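# widefnirs

Monte Carlo simulation of **wide-based illumination and detection in
functional near-infrared spectroscopy (fNIRS)** on a layered slab head
model, built to study whether enlarging scalp optodes (1–15 mm) and
increasing the emitter–detector separation (EDS, 30–50 mm) improves
sensitivity to cortical — including deep sulcal — hemodynamic changes while
suppressing scalp contamination.  The intended audience is researchers in
biomedical optics / neurophotonics who want a self-contained, reproducible
desk-scale version of this simulation study.

## The model

Photon packets are launched uniformly over a disk emitter, normally into a
90 × 150 × 150 mm³ slab head: scalp (6 mm), skull (8 mm), CSF (4 mm),
superficial grey matter (SGM, 10 mm) and white matter (62 mm), plus a
10 × 100 mm sulcal grey-matter prism segmented by depth into DGM1–4
(28–38, 38–48, 48–58, 58–90 mm).  Optical properties at 630 nm per region
(μa, μs in mm⁻¹): scalp/skull (0.019, 7.8, g = 0.89), CSF (0.004, 0.009),
grey matter (0.020, 9.0), white matter (0.080, 8.5, g = 0.90); n = 1.37
throughout.

Transport follows the standard tissue-optics packet convention:

* dimensionless scattering length `s = −ln ξ` consumed as `Σ μs·ℓ` across
  region segments (exact box intersections, no step cap);
* continuous absorption weighting `w = exp(−Σ_r μa_r L_r)` from per-region
  partial path lengths `L_r` — trajectories never depend on μa;
* Henyey–Greenstein scattering; unpolarized Fresnel reflection at the
  tissue–air face; absorbing lateral/bottom faces.

A packet is *detected* when it transmits through the top surface inside the
detector disk.  From the detected set the package computes

* **detected energy** `E = Σ w_i` (full-scale equivalent:
  `5·10⁷ · d² · E / n_launched` packets for an emitter of diameter `d` mm);
* **sensitivity**: percent change of `E` under a region absorption
  perturbation, evaluated *exactly* by common-random-number reweighting
  `E' = Σ w_i · exp(−Δμa · L_i)` (equal to a same-seed rerun to 1e−12);
* **GSPR**, the grey-matter-to-scalp path ratio
  `Σ L_SGM / Σ L_scalp` over detected packets (unweighted path sums).

## Worked example

Sensitivity of the standard system (1 mm optodes, 30 mm EDS) to a +25%
increase in superficial grey-matter absorption (0.020 → 0.025 mm⁻¹),
estimated at desk scale by pooling all exit azimuths with a ring detector at
the true separation:

```python
from widefnirs import (RegionLabel, SourceSpec, DetectorSpec,
                       build_head_model, run_simulation,
                       detected_energy, reweight_energy, percent_change, gspr)
from widefnirs.detection_metrics import select_annulus
from widefnirs.mc_engine import RECORD_TOP_EXITS

model = build_head_model()
res = run_simulation(model, SourceSpec(center=(75, 75), diameter=1.0),
                     DetectorSpec(center=(75, 105), diameter=1.0),
                     n_packets=200_000, seed=7, record_mode=RECORD_TOP_EXITS)
ring = select_annulus(res, (75.0, 75.0), radius=30.0, width=1.0)
e0 = detected_energy(ring)
e1 = reweight_energy(ring, {RegionLabel.SGM: 0.005})  # +25% of 0.020
print(f"detected packets: {ring.n}")
print(f"percent change:   {percent_change(e0, e1):.2f} %")
print(f"GSPR:             {gspr(ring).ratio:.3f}")
```

```
detected packets: 573
percent change:   -2.31 %
GSPR:             0.890
```

The ~2–3% signal drop is the simulated hemodynamic signature of a
seizure-scale blood-volume increase in the cortex; GSPR ≈ 1 says detected
photons accumulate comparable path in cortex and scalp at 30 mm separation
(the ratio grows steeply with EDS — run `widefnirs gspr` to see).

A CLI mirrors the experiment campaigns:

```sh
widefnirs sms --seed 1 --scale 0.001 --replicates 10 --out results/
widefnirs sweep-eds --scale 0.0005 --out results/
widefnirs reproduce-all --scale 0.0005 --out results/
```

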