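{
  "type": "FeatureCollection",
  "description": "Schematic, non-overlapping Atlantic nonbreeding-area polygons (synthetic boundaries for analysis plumbing; swap in real boundaries for real data).",
  "features": [
    {"type": "Feature", "properties": {"name": "North Atlantic"},
     "geometry": {"type": "Polygon", "coordinates": [[[-45, 38], [-20, 38], [-20, 55], [-45, 55], [-45, 38]]]}},
    {"type": "Feature", "properties": {"name": "Canary Current"},
     "geometry": {"type": "Polygon", "coordinates": [[[-28, 12], [-10, 12], [-10, 35], [-28, 35], [-28, 12]]]}},
    {"type": "Feature", "properties": {"name": "Guinea Current"},
     "geometry": {"type": "Polygon", "coordinates": [[[-28, -5], [10, -5], [10, 12], [-28, 12], [-28, -5]]]}},
    {"type": "Feature", "properties": {"name": "Benguela Current"},
     "geometry": {"type": "Polygon", "coordinates": [[[0, -35], [20, -35], [20, -5], [0, -5], [0, -35]]]}},
    {"type": "Feature", "properties": {"name": "Agulhas Current"},
     "geometry": {"type": "Polygon", "coordinates": [[[20, -45], [45, -45], [45, -25], [20, -25], [20, -45]]]}},
    {"type": "Feature", "properties": {"name": "South Atlantic"},
     "geometry": {"type": "Polygon", "coordinates": [[[-40, -55], [-5, -55], [-5, -35], [-40, -35], [-40, -55]]]}},
    {"type": "Feature", "properties": {"name": "Brazil Current"},
     "geometry": {"type": "Polygon", "coordinates": [[[-62, -45], [-40, -45], [-40, -18], [-62, -18], [-62, -45]]]}}
  ]
}
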