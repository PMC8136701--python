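# aedcov

Evaluation of automated external defibrillator (AED) placement against
historical out-of-hospital cardiac arrest (OHCA) locations.

The pipeline:

1. **filtering** — inclusion/exclusion of raw OHCA records (traumatic
   cause, highway, healthcare facility, incomplete address), with
   flowchart-style accounting.
2. **coverage** — nearest-AED straight-line distance per OHCA (haversine
   on a 6,371,000 m sphere, or planar Euclidean), covered under a strict
   < 100 m rule, and stratified summary tables (counts, coverage rate %,
   median / IQR of distances) by municipality stratum or location type.
3. **hotspot** — deterministic greedy detection of uncovered-OHCA
   hotspots (≥ 5 uncovered events in one 100 m disk, no AED nearby) and
   proposed AED placements, with before/after coverage deltas.
4. **overlay** — AED density / overlay detection (> 1 AED per 100 m
   disk) and a coverage-preserving relocation plan: the ordered set of
   public AEDs removable while leaving the covered-OHCA *set* exactly
   unchanged.
5. **synthetic_data** — seeded scenario generator (clustered OHCA
   incidence, sparse AEDs, planted hotspots/overlays with ground-truth
   labels) so everything is testable fully offline.
6. **io_report** — CSV/GeoJSON readers and writers, run configuration,
   and text + CSV report assembly.

## CLI

```sh
# generate a synthetic scenario
aedcov simulate --seed 7 --out data/

# coverage summary (filters applied first)
aedcov coverage --ohca data/ohca.csv --aed data/aed.csv --group-by stratum

# hotspot detection and greedy placement proposals
aedcov hotspots --ohca data/ohca.csv --aed data/aed.csv \
    --radius 100 --min-ohca 5 --out out/hotspots/

# coverage-preserving relocation of public AEDs
aedcov relocate --ohca data/ohca.csv --aed data/aed.csv --public-only --out out/reloc/

# end-to-end report: filter -> coverage -> placements -> deltas -> relocation
aedcov report --ohca data/ohca.csv --aed data/aed.csv --out out/report/
```

Inputs are point tables as CSV (`id,lon,lat,mode,...`) or GeoJSON Point
FeatureCollections (lon-lat order). OHCA files carry
`stratum ∈ {urban, intermediate, rural}`, `location_type ∈ {home, public}`,
`cause`, `setting` and `address_complete`; AED files carry `ownership`
and `available_24_7` (only 24/7 devices participate in coverage).
Coordinates are WGS84 degrees (`mode=geographic`) or metres
(`mode=planar`, used by the simulator).

## Conventions

- Coverage boundary is strict: an OHCA at exactly 100.0 m is uncovered.
- Nearest-neighbour ties break on the lowest AED index; all greedy loops
  are deterministic for fixed inputs.
- Percentiles use linear interpolation; rates and distances are rounded
  to one decimal, with decimal points in all outputs.
- The brute-force pairwise scan is the contractual definition of every
  nearest/within query; the vectorised implementations are tested for
  exact agreement with it.
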