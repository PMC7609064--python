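# Activity-monitor file dialect

`flysleep.dam_io` reads and writes a tab-separated text dialect modeled on
the row layout of widely used beam-break activity monitors, so that real
monitor files need only a thin adapter.  One row per minute, rows in
chronological order at exactly 1-minute spacing, no header line.

## Header columns (both variants)

| col | content | format |
|-----|---------|--------|
| 1 | row index | integer, 1-based |
| 2 | date | `DD Mon YY`, e.g. `01 Jan 21` |
| 3 | time | `HH:MM:SS` |
| 4 | status code | integer; `1` = valid row |
| 5 | channel-status mask | one `0`/`1` character per channel; `1` = tube holds a fly, `0` = empty tube. Distinguishes an *empty channel* from an *inactive (possibly dead) fly*, which is written as a `1` channel with all-zero counts. A plain `0` in this column means "no mask recorded" and all channels are treated as populated. |
| 6–8 | reserved | written as `0` |

## Single-beam variant

Columns 9 … 8+N (N channels, default 32): beam-break count for that
channel in that minute.  Nonnegative integers.

## Multi-beam variant

Each channel occupies 19 consecutive columns:

* 17 per-detector break counts (beams 1–17 along the tube),
* `moves` — number of transitions between **adjacent** beams in that
  minute (locomotion along the tube).  A jump across several beams within
  one sampling tick is counted as the number of beam boundaries crossed,
* `counts` — all beam breaks in the minute, including within-beam events
  (twitches, grooming), so `counts >= moves` at every minute.

The reader infers the variant and channel count from the column count and
the `beam_mode` argument (`single`, `multibeam_moves`, `multibeam_counts`).

## Error handling

* Non-monotonic timestamps → hard error.
* A gap in the 1-minute grid → hard error naming the first missing minute.
* Negative or non-integer counts → hard error.

## Per-minute CSV export

`write_zt_csv` emits `fly_id,zt_min,phase,count` with ZT in minutes
(0–1439) and `phase` ∈ {`day`, `night`} under the half-open convention
(day = ZT [0, photoperiod), so the minute at ZT 720 is night under 12:12).

## Per-fly summary CSV

`sleep_metrics.sleep_summary_frame` emits
`fly_id,<condition fields>,daytime_sleep_min,nighttime_sleep_min,total_sleep_min,n_bouts,mean_bout_len`.
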