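# mousedisco

Tools for designing and analyzing **music place-preference experiments in
rodents**: given a set of candidate audio stimuli and per-animal chamber
dwell times from a multi-chamber ("disco") arena, the package answers three
questions —

1. **Can the animal even hear this?**  Mice hear roughly 2–100 kHz while
   humans hear 20 Hz–20 kHz, so much of a classical piano piece is simply
   below a mouse's range.  `mousedisco.audio` computes spectrograms, the
   amplitude-weighted average frequency and the fraction of spectral energy
   inside any species' hearing range, and can transpose a stimulus up by
   whole octaves (frequency × 2^k at unchanged playback duration) via a
   phase vocoder.
2. **How complex is this music, objectively?**  `mousedisco.complexity`
   scores a track on four axes — *spectral* (mean per-octave-band contrast
   between log peak and log valley magnitudes), *rhythmic* (temporal
   fluctuation of the onset-autocorrelation tempogram), *harmonic*
   (temporal fluctuation of unit-sum 12-class chroma from a constant-Q
   transform) and *dynamic* (std of framewise RMS of the peak-normalized
   signal) — plus recurrence/chroma/tempogram structure maps, per-segment
   scoring and per-dimension track ranking.
3. **Do the animals care?**  `mousedisco.stats` implements the
   chamber-occupancy analysis chain: ROUT outlier calling at FDR level
   Q (median center, robust residual scale from the 68.27th absolute-residual
   percentile, t-distributed residual p-values, step-up flagging), one-way
   ANOVA, pooled-variance pairwise t-tests, and Benjamini–Hochberg step-up
   adjustment q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎·m/j over the family of all C(k,2)
   pairwise comparisons, with significance at q < α.

Because commercial music recordings cannot be redistributed and raw animal
data are rarely deposited, `mousedisco.synth` generates everything needed to
exercise and validate the pipeline: elementary audio fixtures (tones, chord
sequences, click trains, modulated noise), four 2-minute *genre mimics* with
engineered contrasts, and occupancy tables drawn from moment-matched
truncated normals under the physical constraint that one animal's chamber
times cannot exceed the session length.

## Worked example

```python
import mousedisco as md

# a synthetic "classical-like" stimulus: melody over sustained chords,
# energy below 2 kHz, flat dynamics
sig = md.gen_genre_mimics(seed=7)["classical-like"]

prof = md.audibility_profile(sig, md.MOUSE_RANGE)
print(f"average frequency: {prof.average_frequency_hz:.1f} Hz")
print(f"mouse-audible energy fraction: {prof.audible_fraction:.3f}")

ci = md.complexity_indices(sig)
print(f"indices: spectral={ci.spectral:.3f} rhythmic={ci.rhythmic:.4f} "
      f"harmonic={ci.harmonic:.4f} dynamic={ci.dynamic:.4f}")

table = md.gen_occupancy(md.fig4_spec(seed=7))   # 12 animals, 4 chambers
res = md.ChamberPreference(table).fit(outlier_q=0.01, alpha=0.05)
print(res.summary())
```

prints

```
average frequency: 645.7 Hz
mouse-audible energy fraction: 0.012
indices: spectral=6.659 rhythmic=0.0349 harmonic=0.1575 dynamic=0.0186

Chamber-preference analysis
============================================================
conditions: EDM, Mozart, Rock, TaylorSwift
ROUT outliers (Q=0.01): 0 flagged (excluded from tests, retained in report)

condition           mean (s)  raw mean (s)    n
EDM                   1013.7        1013.7   12
Mozart                 355.6         355.6   12
Rock                   626.3         626.3   12
TaylorSwift            923.0         923.0   12

one-way ANOVA: F(3, 44) = 3.969, p = 0.01375

pair                                t   df     p_raw         q  sig(q<0.05)
EDM vs Mozart                   3.183   22    0.0043    0.0258  *
EDM vs Rock                     1.735   22    0.0968    0.1451
EDM vs TaylorSwift              0.331   22    0.7436    0.7436
Mozart vs Rock                 -2.202   22    0.0384    0.0769
Mozart vs TaylorSwift          -2.823   22    0.0099    0.0297  *
Rock vs TaylorSwift            -1.361   22    0.1873    0.2248
```

Reading: the classical-like stimulus sits almost entirely below the mouse
hearing range (1.2% audible energy, average frequency ≈ 646 Hz), and in this
simulated session set the animals spent significantly less time in the
Mozart chamber than in the EDM and pop chambers (q < 0.05 after BH
adjustment over all six pairwise comparisons), while the remaining pairs do
not separate — the pattern the occupancy preset is built to emulate.

The same stages are scriptable from the shell:

```bash
disco simulate audio --kind edm-like --duration 120 --seed 7 --out edm.wav
disco audio profile --in edm.wav --range mouse --out profile.json
disco audio complexity --in edm.wav --segment-s 120 --out indices.csv --plots figs/
disco simulate occupancy --preset fig4 --n 12 --seed 7 --out occ.csv
disco stats preference --in occ.csv --q 0.01 --alpha 0.05 --out report.json
disco run --config run.yaml          # all stages, one reproducible directory
```

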