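# motorquant

Quantification pipelines for kinesin motor-activity assays in cells and in
vitro.  Cell biologists studying microtubule motors (and their
small-molecule inhibition) read motor activity out of microscopy in several
standard ways; this package implements five of those readouts as one
tested, scriptable toolkit, together with a synthetic-data generator that
produces every input with known ground truth so each pipeline can be
validated end to end without real acquisitions:

1. **Golgi dispersion** (fixed cells) — per-cell Golgi integrity
   `SDᵢ/√mean` over a 10-px dilation of the segmented nucleus.  High values
   = compact perinuclear Golgi (motors inhibited); low values = dispersed
   (motors active).  For Poisson shot noise the statistic is exactly 1
   regardless of exposure, which is what makes it comparable across
   experiments.
2. **Neurite tip accumulation** (fixed cells) — distal/proximal mean
   fluorescence ratio; active motors pile up at microtubule plus-ends in
   the tip.
3. **Peroxisome redistribution** (live two-channel time lapse) — organelles
   segmented per frame by local adaptive thresholding; mean distance of all
   object pixels from the cell centre vs time, plus motor recruitment
   (488-nm intensity on the objects).
4. **Microtubule sliding** (photoconversion time lapse) — bleach
   correction, motile fraction per frame
   `%MF = 100·(microtubule pixels outside the initial zone)/(total)`, and
   the sliding rate as the best-R² initial-segment slope (≥ 4 points,
   %·min⁻¹).
5. **Single-molecule TIRF motility** (trajectory tables) — lifetime and
   microtubule-overlap filtering; classification into motile (> 250 nm
   start-to-end displacement) / immotile (< 250 nm, 2.5–10 s dwell) /
   discarded; exponential run-length and normal velocity fits with
   2,000-resample bootstrap CIs; event frequencies per µm of microtubule
   per minute; Welch t and Kolmogorov–Smirnov comparisons between ±drug
   conditions.

See `docs/methods.md` for the models, parameter defaults, and the design
decisions behind each pipeline.

## Worked example

Simulate a single-molecule TIRF field with known ground truth, then analyse
it:

```sh
echo '{"landing_rate_per_um_min": 4.0}' > cfg.json
motorquant simulate smtracks --seed 7 --config cfg.json --out sim/
motorquant smtracks --tracks sim/tracks.csv --mt-mask sim/mt_mask.tif \
    --pixel-nm 107 --duration-min 2 --boot 2000 --seed 7 --out stats/
```

which prints

```
wrote smtracks dataset to sim
INFO motorquant.smtracks: filter_tracks: dropped 28 of 316 tracks
motile=169 immotile=104 freq_motile=2.0225/um/min mean_run=1211 nm
```

The generator landed motors on ~42 µm of simulated microtubule for 2 min at
4 landings·µm⁻¹·min⁻¹ with a true mean run length of 1200 nm and 70%
motile fraction.  The pipeline dropped 28 tracks that were too short-lived,
classified 169 motile and 104 immotile events, and recovered a
cutoff-corrected exponential mean run of 1211 nm — the generating value
sits comfortably inside the bootstrap 95% CI of (1043, 1394) nm recorded in
`stats/stats.json`.  The same pattern works for the image-based assays:

```sh
motorquant simulate sliding --seed 3 --out sim2/
motorquant sliding --movie sim2/movie.tif --pixel-nm 100 --out rate/
# rate=4.991 %/min (R2=0.9999, n=11)   — generated at 5 %/min
```

Every command writes a `manifest.json` with the merged configuration, and
re-running from the same manifest reproduces byte-identical outputs.

Library use mirrors the CLI: `motorquant.gen_trajectories`,
`filter_tracks`, `classify_events`, `summarize_events`,
`compare_conditions`, and the image pipelines `golgi_dispersion`,
`perox_time_series`, `bleach_correct` → `motile_fraction_series` →
`sliding_rate`.

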