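# speechtrack

Lag-resolved tracking of speech features in intracranial high-frequency-band
(HFB, 65–125 Hz) signals, packaged with a synthetic ground-truth generator so
the entire analysis chain is testable without any recorded data.

The pipeline mirrors a naturalistic speech-perception ECoG analysis:

1. **synthetic_data** — annotated audio (speech-like harmonic source with an
   f0 random walk and syllabic amplitude modulation, music/noise background,
   configurable SNR in noisy-speech windows) plus multichannel raw neural
   signals whose 65–125 Hz amplitude follows the speech envelope at a known
   gain and lag, on top of pink noise and 50 Hz line noise.
2. **preprocess** — channel rejection, zero-phase line-noise notch, common
   average reference per grid, Gabor-wavelet amplitude in 1 Hz bins averaged
   over 65–125 Hz, downsampled to 100 Hz and z-scored over the analysis
   fragments.
3. **audio_features** — constant-Q cochlear-style spectrogram (128 log-spaced
   bins, 180–7200 Hz, 8 ms frames), 1-D spectral envelope at 100 Hz,
   autocorrelation pitch contour (0 = unvoiced) and an intensity-threshold
   sound ON/OFF vector.
4. **fragments** — greedy extraction of non-overlapping 4-s speech /
   nonspeech / noisy-speech windows from the word-level annotation
   (internal pauses ≤ 500 ms), binary speech ON/OFF vectors per fragment.
5. **tracking_stats** — per-fragment lag-resolved Spearman correlation
   (−100…500 ms, 10 ms grid), Fisher transform, Bonferroni-corrected t
   contrasts: speech preference, envelope tracking, STG-reference coupling,
   isolated-vs-mixed noise filtering, signed-r² localizer statistic.
6. **regression_suite** — per-fragment lag alignment, ON/OFF OLS with a
   fragment-order permutation F null, partial Spearman correlations
   (pitch | envelope and envelope | pitch), residual group comparisons
   (Kruskal–Wallis, Dunn post hocs, two-way rank ANOVA), hand-covariate
   control with Wilcoxon comparisons, and chi-square independence tests
   (optional Yates correction).
7. **pipeline / cli** — orchestration with seeded determinism and TSV/JSON
   reports carrying a config hash.

## CLI

```sh
speechtrack simulate --seed 1 --n-speech 10 --n-nonspeech 10 --out fix/
speechtrack fragments --annotation fix/annotation.tsv --out frags.tsv
speechtrack preprocess --in fix/neural.f32 --fragments-tsv frags.tsv --out hfb.f32
speechtrack features --wav fix/audio_mixed.wav --out feats.tsv
speechtrack track --hfb hfb.f32 --features feats.tsv --fragments frags.tsv \
    --analysis envelope --out results/
speechtrack run --seed 1 --out run/        # full synthetic pipeline
speechtrack regress --table '114,61,107;127,62,138'   # chi-square helper
```

File formats are plain: WAV (float32), Praat TextGrid + TSV mirror for the
annotation, raw float32 + JSON sidecar for neural arrays, TSV/JSON outputs.

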