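"""Qp/Qs in shunt-free subjects, before and after offset correction.

Pairs of aorta and main-pulmonary-artery studies are generated with equal
true stroke volume (no shunt), each with its own planted background offset.
Uncorrected, the Qp/Qs ratio scatters around 1; after interpolation-based
correction it should tighten toward unity.
"""

import dataclasses as dc

import numpy as np

from pcflow import (
    CorrectionConfig,
    VesselWaveform,
    build_stationary_mask,
    correct_series,
    fit_offset_surface,
    generate_study,
    qp_qs,
    time_averaged_velocity,
    volume_flow,
)
from pcflow.synth import compact_config

rng = np.random.default_rng(99)
cc = CorrectionConfig()
pre_ratios, post_ratios = [], []

for subject in range(10):
    sv = float(rng.normal(80, 10))  # shared true stroke volume, ml
    flows = {}
    for vessel, systole_fraction in (("MPA", 0.48), ("aorta", 0.40)):
        coef = (float(rng.normal(0, 1.5)), float(rng.normal(0, 0.8)),
                float(rng.normal(0, 0.8)))
        cfg = compact_config(seed=int(rng.integers(0, 2**31 - 1)),
                             offset_order=1, offset_coefficients=coef,
                             vessel_label=vessel)
        area = np.pi * cfg.layout.vessel_radius_cm**2
        rr = 60.0 / cfg.heart_rate
        wf = VesselWaveform(systole_fraction=systole_fraction).with_stroke_volume(
            sv, area, rr)
        sampled = area * wf.sample(cfg.n_phases, rr).sum() * rr / cfg.n_phases
        wf = dc.replace(wf, peak=wf.peak * sv / sampled,
                        diastolic=wf.diastolic * sv / sampled)
        study, _ = generate_study(dc.replace(cfg, waveform=wf))
        roi = study.roi("vessel")
        mask = build_stationary_mask(study.in_vivo, [], cc)
        surface = fit_offset_surface(time_averaged_velocity(study.in_vivo), mask, 1)
        flows[vessel] = (
            volume_flow(study.in_vivo, roi),
            volume_flow(correct_series(study.in_vivo, surface), roi),
        )
    pre_ratios.append(qp_qs(flows["MPA"][0], flows["aorta"][0]))
    post_ratios.append(qp_qs(flows["MPA"][1], flows["aorta"][1]))

pre, post = np.array(pre_ratios), np.array(post_ratios)
print("Qp/Qs per subject (uncorrected -> corrected):")
for i, (a, b) in enumerate(zip(pre, post)):
    print(f"  subject {i}: {a:.3f} -> {b:.3f}")
print(f"\nuncorrected: {pre.mean():.3f} +/- {pre.std(ddof=1):.3f}")
print(f"corrected:   {post.mean():.3f} +/- {post.std(ddof=1):.3f}")
# in a shunt-free cohort the ratio is ~1; the offset-driven spread of the
# uncorrected ratios collapses once the background field is subtracted.
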