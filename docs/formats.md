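# File formats

## Measurement session (JSON, schema version 1)

One file per observer × radiograph study × round × method. Keys are
written sorted and coordinates rounded to 4 decimals, so serialisation
is byte-stable.

```json
{
  "schema_version": 1,
  "observer_id": "E1",
  "group": "expert",
  "method": "software",
  "round": 1,
  "radiograph_id": "XR007",
  "curves": [
    {
      "curve_id": "C01",
      "cranial_candidates": [
        {"vertebra": "T5", "p1": [103.2, 410.7], "p2": [188.9, 399.4]},
        {"vertebra": "T6", "p1": [101.0, 455.2], "p2": [190.3, 431.1]}
      ],
      "caudal_candidates": [
        {"vertebra": "T12", "p1": [99.4, 702.8], "p2": [185.1, 760.2]}
      ]
    }
  ]
}
```

Constraints enforced on read:

- `group` ∈ {expert, novice}; `method` ∈ {software, manual}; `round` ∈ {1, 2, 3};
- every curve id unique within the session;
- software curves: ≥ 1 cranial and ≥ 1 caudal candidate, no duplicate
  vertebra within a role, `p1 ≠ p2` per endplate;
- manual curves instead carry only `"cobb_deg": <degrees>` (film
  readings have no landmarks).

Landmark coordinates are continuous image pixels: `[x, y]` with the
origin at the top-left corner, x growing rightward (columns) and y
growing downward (rows).

## Study table (CSV, long format)

One row per curve × observer × round × method:

```
curve_id,observer_id,group,method,round,cobb_deg,cranial_vertebra,caudal_vertebra
C01,E1,expert,software,1,23.4,T6,T12
```

`cobb_deg` carries one decimal place (the instrument scale). The
vertebra columns are empty for manual rows. A complete design with 35
curves, 8 observers, 3 rounds and 2 methods has 1680 rows.

## Analysis report

`analyze` writes `<prefix>.csv` (one row per comparison: comparison,
method, MBE, SD, gl, SE, MDC95, ICC, CI95 bounds, Landis–Koch label,
Shapiro–Wilk p, outliers removed) and `<prefix>.json`, which adds the
method-agreement block (MBE, SD, SEM, MDC95, ICC, Bland–Altman bias
and limits of agreement) and the ANOVA/Tukey and t-test blocks.
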