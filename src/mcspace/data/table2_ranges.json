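{
  "version": 1,
  "provenance": "packaged-Table2",
  "description": "13 key oral-macrocycle-druglike property ranges (80% coverage of the oral macrocycle drug set)",
  "entries": [
    {"mold_id": 35, "name": "Spiro rings", "lo": 0.0, "hi": 0.0, "modality": "n/a"},
    {"mold_id": 46, "name": "PeriphO/PeriphHA", "lo": 0.30, "hi": 0.67, "modality": "A"},
    {"mold_id": 79, "name": "St. dev of gap size/N", "lo": 0.06, "hi": 0.26, "modality": "A"},
    {"mold_id": 8, "name": "tPSA", "lo": 50.0, "hi": 230.0, "modality": "A"},
    {"mold_id": 16, "name": "(PeriphN+1)/(PeriphO+1)", "lo": 0.13, "hi": 0.50, "modality": "B"},
    {"mold_id": 64, "name": "Substituent Fsp3", "lo": 0.22, "hi": 1.00, "modality": "B"},
    {"mold_id": 77, "name": "Min gap size/N", "lo": 0.0, "hi": 0.13, "modality": "B"},
    {"mold_id": 6, "name": "CLogP", "lo": 2.40, "hi": 6.00, "modality": "A"},
    {"mold_id": 76, "name": "Max gap size/N", "lo": 0.24, "hi": 0.64, "modality": "C"},
    {"mold_id": 89, "name": "Peptide character index", "lo": 0.0, "hi": 0.44, "modality": "B"},
    {"mold_id": 82, "name": "Restricted fraction", "lo": 0.0, "hi": 0.42, "modality": "C"},
    {"mold_id": 18, "name": "ChiralCenters/HA", "lo": 0.02, "hi": 0.33, "modality": "A"},
    {"mold_id": 22, "name": "RingHet/N", "lo": 0.06, "hi": 0.31, "modality": "B"}
  ]
}
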