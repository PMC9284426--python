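# copiiscreen

Analysis toolkit for image-based **double-knockdown secretion screens**: the
experimental design in which a library of siRNAs spotted on chamber slides
(384 spots per chamber) is combined with a chamber-wide "background"
knockdown of a COPII inner-coat paralog (SEC23A or SEC23B), and the
ER-to-surface transport of a synchronized reporter (e.g. VSVG-tsO45) is read
out per cell by automated microscopy.  The package is written for screen
analysts: it turns per-cell images or tables into spatially normalized
transport scores, applies plate quality control and replicate aggregation,
and calls **synergistic (functional) interactions** between library genes
and the COPII background.  Companion modules quantify 3D puncta (ER exit
sites, COPI carriers), focal adhesions, and biotin-release (RUSH) transport,
and a synthetic-data module generates plates and image stacks with known
ground truth so every stage is testable without any raw-data download.

## The statistic

Each cell contributes a transport ratio — surface reporter signal over
total reporter signal.  For a spot *i* with mean per-cell ratio *x&#7522;*,
the **transport score** is

```
score_i = (x_i − X_i) / MAD_i
```

where *X&#7522;* is the median of the transport ratios in the 5×5 window of
spots centered on *i* (25 values on a full interior window, the center
included) and *MAD&#7522;* is the median absolute deviation of that window,
with **no** 1.4826 consistency constant.  Negative scores mean transport
inhibition, positive scores acceleration.  The score is invariant under
affine rescaling of the ratios and removes smooth plate effects.

Hit calling compares the double knockdown against the additive expectation
of its single knockdowns: a condition is a **synergy hit** when its
median score over ≥ 3 biological replicates is a strong effect
(|score| ≥ 1.5, a threshold anchored on coatomer positive controls) *and*
`|double − (single_gene + single_background)| > 1` score unit.

## Worked example

Simulate a small screen (one 8×12 chamber spotted with 60 library siRNAs
plus controls, three replicates, control and SEC23A backgrounds, two
planted synergistic pairs with interaction −0.25 ratio units) and run the
full pipeline:

```bash
cat > config.json <<'JSON'
{"out_dir": "run", "seed": 5,
 "simulate": {"n_replicates": 3, "n_chambers": 1, "n_rows": 8, "n_cols": 12,
              "n_sample_sirnas": 60, "n_genes": 30, "n_planted": 2,
              "backgrounds": ["control", "SEC23A"]}}
JSON
copiiscreen run-all config.json
# screen run complete -> run
```

`run/hits.csv` (ranked by |double score|):

```
      gene sirna_id background  single_gene_score  single_background_score  double_score  additive_expectation  difference effect_class  is_hit
0  GENE020   si0020     SEC23A             -2.174                    0.195       -20.040                -1.979     -18.061    inhibitor    True
1  GENE025   si0025     SEC23A             -0.091                    0.195       -18.724                 0.104     -18.827    inhibitor    True
2  GENE020   si0050     SEC23A             -0.956                    0.195       -15.109                -0.761     -14.349    inhibitor    True
3  GENE025   si0055     SEC23A              1.253                    0.195        -7.862                 1.447      -9.310    inhibitor    True
```

The two planted pairs (`GENE020×SEC23A`, `GENE025×SEC23A`, recorded in
`run/truth.json`) are recovered by both of their independent siRNAs and
nothing else is called: each double-knockdown score is strongly negative
(transport inhibition), far from the additive expectation of its single
knockdowns, while all 6 plates passed quality control
(`run/plate_qc.json`) and all 114 (siRNA, background) conditions carried
the full 3 replicates (`run/gene_scores.csv`).  Every exclusion the
pipeline makes — failed plates, thin spots, under-replicated conditions —
is written as a machine-readable record to `run/log.jsonl`.

The imaging subpipelines run the same way, e.g.

```bash
copiiscreen spots3d --seed 1 --out spots_out \
  --conditions '{"control": {"n_puncta": 10}, "kd": {"n_puncta": 4}}'
copiiscreen adhesions --seed 1 --out fa_out
copiiscreen rush --seed 1 --out rush_out \
  --conditions '{"control": {"release_mean": 0.5}, "kd": {"release_mean": 0.3}}'
```

Library use mirrors the CLI: `simulate_plate` / `score_plate` /
`plate_qc` / `aggregate_replicates` / `call_hits` for screens;
`segment_nuclei` / `segment_cells` / `per_cell_transport_ratio` for 2D
fields; `preprocess_stack` / `detect_seeds` / `segment_spots` /
`exclude_large_clusters` / `per_cell_spot_stats` for 3D puncta;
`select_focus_plane` / `fa_segment` / `fa_stats` for adhesions.

## Layout file format

A chamber layout is a flat CSV (or an equivalent JSON) with 0-based,
row-major grid coordinates:

```
chamber_id,row,col,sirna_id,target_gene,control_role,background
C1,0,0,si0001,GENE001,sample,control
C1,0,1,Scramble,,negative,control
C1,0,2,si_COPB1,COPB1,positive,control
...
```

`control_role` is one of `sample`, `positive`, `negative`,
`transfection_qc`; `background` (the chamber-wide suspension siRNA) is
constant per chamber.  `copiiscreen simulate plate --out dir` writes a
complete 16×24 example.

## Limitations worth knowing

The windowed median/MAD score is *self-normalizing*: on a plate with no
real spot-to-spot biology its null distribution is pivotal with scale
≈ 1.5 regardless of how small the technical noise is.  Consequences of
this — for null-plate calibration and for the false-positive behavior of
the additivity-difference hit rule when many library genes carry
persistent strong single effects — are laid out in
[docs/methods.md](docs/methods.md).
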