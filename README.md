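# flysleep

Quantification pipeline for *Drosophila* sleep–courtship experiments:
activity-monitor sleep scoring, video-ethogram window scoring,
courtship/mating-latency analysis, photobleach-corrected calcium-trace
ΔF/F0, and the accompanying statistical decision procedures — plus
synthetic-data generators with ground truth for every stage.

It is written for behavioral neuroscientists and chronobiologists who
analyze beam-break activity-monitor data (and the surrounding assays) and
want the standard scoring rules as explicit, tested, scriptable code.

## What it computes

**Sleep.**  Activity arrives as beam-break counts in 1-min bins; sleep is
a maximal run of zero-count minutes with length ≥ 5 min.  From the scored
series the package computes day/night totals (day = ZT [0,12) h under a
12:12 light:dark cycle), 30-min sleep profiles, per-night sleep, bout
statistics, thermogenetic sleep change (activation − baseline phase
sleep), Tukey box summaries, and a dead-fly flag.  Multi-beam monitors
are supported in both "moves" (adjacent-beam transitions) and "counts"
(all breaks) modes; counts ≥ moves minute-wise, so counts-mode sleep can
only be shorter.

**Ethogram windows.**  Per-second labels for the first 5 min of each hour
in ZT 18–24 are partitioned into %sleep / %courting / %wake-not-courting,
with the human scorer's edge rule made explicit: in-window immobility is
sleep only if its full run, followed into context beyond the window
edges, reaches 5 min.

**Courtship.**  Courtship index CI = courting time / min(10 min, time to
copulation) after initiation (undefined when no initiation); latencies
censored at the 2-h observation end; groups compared with a log-rank test
implemented from its O/E/V risk-table formula,

χ² = (Σ(Oₜ − Eₜ))² / ΣVₜ,  Eₜ = dₜ·nₐₜ/Nₜ,
Vₜ = dₜ(Nₜ−dₜ)nₐₜn_bₜ / (Nₜ²(Nₜ−1)).

**Calcium.**  F(t) = A·e^(−kt) + C fit to two transient-free windows
(30–60 s pre-ATP, 150–180 s post-washout); the decaying component is
subtracted, F0 = mean detrended intensity in the 30 s before ATP, and
ΔF/F0 = (F − F0)/F0 with a peak response over perfusion + 60 s.

**Statistics.**  Normality-gated test selection (D'Agostino–Pearson →
Mann-Whitney / Brown–Forsythe → Welch / Student), two-way interaction
ANOVA with Sidak/Tukey/Dunnett post-hoc families, and the dual-control
screen-hit rule (experimental must differ from both its GAL4 and UAS
controls, same direction).

**Simulation.**  A two-state (wake/sleep) Markov chain per minute with
phase-dependent transition probabilities generates activity recordings
with hidden-state ground truth; run lengths are geometric, giving
closed-form expectations for scored sleep that the tests use as oracles.
Generators also produce multi-beam recordings, censored latency trials
and GCaMP-like traces, all bit-reproducible from a seed.

See `docs/methods.md` for models, conventions and known limitations, and
`docs/dam_dialect.md` for the monitor-file text format.

## Worked example

Simulate a pairing-by-nutrition experiment and test the interaction:

```sh
flysleep report --n-per-cell 32 --seed 7 --out demo
```

`demo/cell_means.csv` then contains the nighttime-sleep table (minutes,
mean ± SD over 32 flies/cell):

```
sex_pairing,diet,mean,std,count
MF,deprived,495.15625,121.18716779055767,32
MF,fed,197.90625,124.41303722136664,32
MM,deprived,575.4375,104.31773346909446,32
MM,fed,580.71875,105.7441325681035,32
```

and `demo/stats.json` reports `"interaction_p": 1.13e-11` with the
Sidak-adjusted pairwise contrasts.  Read: female-paired males sleep far
less than male-paired males when protein-fed (198 vs 581 min/night), the
deficit largely disappears under yeast deprivation (495 vs 575), and the
pairing × diet interaction is highly significant — the structure the
simulator is parameterized to emulate.

The same analyses run from files: `flysleep simulate` writes monitor
files + ground truth, `flysleep score-sleep` scores them to per-fly CSVs,
and `flysleep courtship`, `flysleep calcium`, `flysleep score-ethogram`,
`flysleep screen` cover the other assays (all take `--help`).

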