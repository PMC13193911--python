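{
  "description": "Lesion-level cohort schema: one row per treated radiosurgical target.",
  "missing_encoding": "empty cell",
  "fields": {
    "patient_id": {"type": "string", "required": true, "doc": "Opaque patient identifier; the unit of grouped validation and cluster resampling."},
    "lesion_id": {"type": "string", "required": true, "doc": "Opaque target identifier, unique within patient."},
    "age_years": {"type": "number", "unit": "years", "range": [0, null], "doc": "Age at diagnosis."},
    "sex": {"type": "category", "levels": ["M", "F"]},
    "kps": {"type": "integer", "levels": [40, 50, 60, 70, 80, 90, 100], "doc": "Karnofsky Performance Status before radiosurgery; off-grid values are treated as missing."},
    "volume_cm3": {"type": "number", "unit": "cm3", "range": [0, null], "exclusive_min": true, "doc": "Pre-treatment contrast-enhancing target volume including necrosis."},
    "anatomic_loc": {"type": "category", "levels": [1, 2, 3, 4, 5, 6], "doc": "1 frontal, 2 parietal, 3 occipital, 4 temporal, 5 cerebellar, 6 other/deep midline."},
    "tumor_loc": {"type": "category", "levels": [1, 2, 3], "doc": "1 cortical/sub-cortical, 2 deep-seated or midline, 3 multifocal."},
    "dose_gy": {"type": "number", "unit": "Gy", "range": [0, null], "exclusive_min": true, "doc": "Prescription dose at the covering isodose surface."},
    "isodose_pct": {"type": "number", "unit": "%", "range": [0, 100], "exclusive_min": true, "doc": "Prescription isodose line as percent of maximum dose."},
    "max_gy": {"type": "number", "unit": "Gy", "range": [0, null], "exclusive_min": true, "doc": "Maximum dose; approximately prescription / (isodose/100)."},
    "coverage": {"type": "number", "range": [0, 1], "doc": "Fraction of target volume covered by the prescription isodose."},
    "mgmt": {"type": "category", "levels": ["methyl", "unmethyl"], "doc": "MGMT promoter methylation."},
    "egfr": {"type": "category", "levels": ["ampl", "unampl", "mut", "unmut"], "doc": "EGFR status as recorded in source data (amplification and mutation vocabularies both occur)."},
    "pten": {"type": "category", "levels": ["mut", "umut"]},
    "tert": {"type": "category", "levels": ["mut", "unmut"]},
    "chr7p10q": {"type": "category", "levels": ["yes", "no"], "doc": "Combined chromosome 7 gain / 10 loss signature."},
    "time_months": {"type": "number", "unit": "months", "range": [0, null], "exclusive_min": true, "required": true, "doc": "Time from radiosurgery to first imaging documenting local failure, or to last imaging follow-up if censored."},
    "event": {"type": "integer", "levels": [0, 1], "required": true, "doc": "1 = local failure observed, 0 = right-censored."}
  }
}
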