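# Coronary tree file formats

## JSON schema `ffru-tree/1`

A tree file is a single JSON object:

```json
{
  "schema": "ffru-tree/1",
  "units": {"length": "mm"},
  "metadata": {"name": "demo-lad"},
  "root": "root",
  "segments": [
    {"id": "root", "parent": null, "length": 20.0, "d_prox": 4.0, "d_dist": 4.0},
    {"id": "lad",  "parent": "root", "length": 40.0, "d_prox": 3.3, "d_dist": 2.8,
     "diameter_profile": [[0.0, 3.3], [20.0, 3.1], [40.0, 2.8]]}
  ],
  "stenoses": [
    {"segment": "lad", "start": 10.0, "length": 5.0,
     "severity": 0.5, "ref_diameter": 3.2}
  ]
}
```

* `units.length` — one of `"m"`, `"mm"`, `"cm"`; applies to every length,
  diameter, arc position and `ref_diameter` in the file. The in-memory tree
  is always SI metres regardless of the declared unit.
* `segments[]` — required fields `id`, `parent` (null for the root),
  `length`, `d_prox`, `d_dist`. Optional `diameter_profile`: ordered
  `[arc_position, diameter]` pairs with strictly increasing positions, the
  first at 0 and the last at `length`, endpoint diameters matching
  `d_prox`/`d_dist`. Without a profile the lumen tapers linearly.
* `stenoses[]` — each lesion names its `segment`, its `start` arc position
  and `length` along the centerline, a fractional diameter reduction
  `severity` in (0, 1), and the healthy `ref_diameter` at the lesion. The
  lumen diameter inside the lesion is `ref_diameter * (1 - severity)`.
* Structure: exactly one root, no cycles, every non-root segment has one
  parent. Terminal segments are the outlets. Any branching order is
  accepted (bifurcations, trifurcations, ...).

`load_tree` raises a `SchemaError` naming the offending field for malformed
records and a `TreeStructureError` for duplicate ids, cycles or multiple
roots. `validate_tree` returns the full list of invariant violations
without raising.

## CSV dialect

Two files, lengths in mm by default (`units=` argument of `load_tree_csv`):

`segments.csv`

    id,parent,length,d_prox,d_dist
    root,,20,4,4
    lad,root,40,3.3,2.8

`stenoses.csv` (optional)

    segment,start,length,severity,ref_diameter
    lad,10,5,0.5,3.2

Diameter profiles are JSON-only.
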