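# foxmove

Movement-tactic analysis for daily GPS telemetry of territorial predators,
plus a synthetic trajectory generator so the whole pipeline runs at desk
scale without field data.

The pipeline:

1. **traj_io** — read telemetry CSVs (lon/lat or planar km), project to a
   local azimuthal equal-area plane, thin tracks to one random fix per day,
   assign resource seasons (summer: May 15 – Oct 31; winter: Nov 1 – May 14),
   classify habitat against world polygons, and optionally screen gross
   location errors with a speed filter.
2. **homerange** — adaptive local convex hull (a-LoCoH) utilization
   distributions: 95% home ranges and 50% core areas, seasonal overlap and
   centroid shift, and a sample-size asymptote diagnostic.
3. **tactics** — classify each animal-season as resident / disperser /
   insufficient, segment dispersal events (departure from the prior range,
   settlement of ≥8 consecutive days in a new area, or death/track end),
   compute track metrics (cumulative km, CSLD ratio, bearing, daily speed,
   main substrate), and export a right-censored winter survival table.
4. **excursions** — detect out-and-back trips beyond the 95% isopleth,
   flag excursions with a one-sided Hampel filter
   (median + 3 × MAD of Tukey-transformed centroid distances), label
   sea-ice trips as commuting, and report weekly frequencies.
5. **stats_report** — two-sided permutation t-tests (exact enumeration for
   small samples, 9999 draws otherwise) and the run orchestration.
6. **simulate** — Ornstein–Uhlenbeck residents with planted excursion and
   commuting bouts, correlated-walk dispersers with controllable distance /
   speed / tortuosity / substrate, cohort generation with tactic-specific
   mortality, all fully seeded.

## Tests

```bash
python -m pytest -q tests/
```

## CLI

```bash
# full demo: simulated cohort -> every summary table, deterministic per seed
foxmove run-all --seed 42 --outdir runs/demo

# with your own config (YAML; see foxmove/pipeline.py DEFAULT_CONFIG)
foxmove run-all --config config.yaml --outdir runs/mine

# individual verbs
foxmove simulate --seed 3 --outdir runs/sim
foxmove thin runs/sim/telemetry.csv --seed 3 --out runs/thinned.csv
foxmove stats values.csv --group-col group --value-col value
```

Each run writes `telemetry.csv`, `tactic_labels.csv`, `dispersal_events.csv`,
`dispersal_summary.csv`, `home_ranges.csv`, `seasonal_shift.csv`,
`excursions.csv`, `excursion_frequency.csv`, `survival.csv` (simulated runs)
and a `manifest.json`; re-running with the manifest's config reproduces the
tables byte-for-byte.

## Notes

- Coordinates are planar kilometres on a Lambert azimuthal equal-area
  projection (areas are first-class outputs); the simulator emits planar km
  directly.
- The a-LoCoH `a` parameter defaults to the maximum pairwise distance per
  animal-season (a documented, reproducible stand-in for interactive
  tuning); hulls use the cumulative neighbour-distance rule, so isopleths
  only span the full convex hull for much larger `a`.
- LoCoH areas creep upward with sample size; the asymptote diagnostic
  exposes its tolerance band (and a confirmation margin) for that reason.
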