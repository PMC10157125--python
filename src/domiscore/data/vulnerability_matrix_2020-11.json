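{
 "schema_version": "1",
 "grid_version": "2020-11",
 "note": "Exemplar vulnerability-penalty matrix. The ventilation/young-children and surface-area/visual-disability rules are documented; all rules marked 'placeholder (synthetic)' are illustrative reconstructions.",
 "rules": [
  {
   "vulnerability": "young_children_u4",
   "variable_id": "ventilation",
   "trigger_threshold": 3,
   "penalty_points": 1,
   "note": "documented rule"
  },
  {
   "vulnerability": "visual_disability",
   "variable_id": "surface_area",
   "trigger_threshold": 1,
   "penalty_points": 1,
   "note": "documented rule"
  },
  {
   "vulnerability": "young_children_u4",
   "variable_id": "lead_paint",
   "trigger_threshold": 1,
   "penalty_points": 1,
   "note": "placeholder (synthetic)"
  },
  {
   "vulnerability": "young_children_u4",
   "variable_id": "fall_protection",
   "trigger_threshold": 1,
   "penalty_points": 1,
   "note": "placeholder (synthetic)"
  },
  {
   "vulnerability": "young_children_u4",
   "variable_id": "window_guards",
   "trigger_threshold": 1,
   "penalty_points": 1,
   "note": "placeholder (synthetic)"
  },
  {
   "vulnerability": "young_children_u4",
   "variable_id": "mold",
   "trigger_threshold": 2,
   "penalty_points": 1,
   "note": "placeholder (synthetic)"
  },
  {
   "vulnerability": "elderly_o70",
   "variable_id": "heating",
   "trigger_threshold": 2,
   "penalty_points": 1,
   "note": "placeholder (synthetic)"
  },
  {
   "vulnerability": "elderly_o70",
   "variable_id": "fall_protection",
   "trigger_threshold": 1,
   "penalty_points": 1,
   "note": "placeholder (synthetic)"
  },
  {
   "vulnerability": "elderly_o70",
   "variable_id": "stair_safety",
   "trigger_threshold": 1,
   "penalty_points": 1,
   "note": "placeholder (synthetic)"
  },
  {
   "vulnerability": "elderly_o70",
   "variable_id": "entrance_accessibility",
   "trigger_threshold": 2,
   "penalty_points": 1,
   "note": "placeholder (synthetic)"
  },
  {
   "vulnerability": "elderly_o70",
   "variable_id": "bathroom_shower",
   "trigger_threshold": 2,
   "penalty_points": 1,
   "note": "placeholder (synthetic)"
  },
  {
   "vulnerability": "physical_disability",
   "variable_id": "entrance_accessibility",
   "trigger_threshold": 1,
   "penalty_points": 1,
   "note": "placeholder (synthetic)"
  },
  {
   "vulnerability": "physical_disability",
   "variable_id": "interior_circulation",
   "trigger_threshold": 1,
   "penalty_points": 1,
   "note": "placeholder (synthetic)"
  },
  {
   "vulnerability": "physical_disability",
   "variable_id": "surface_area",
   "trigger_threshold": 1,
   "penalty_points": 1,
   "note": "placeholder (synthetic)"
  },
  {
   "vulnerability": "physical_disability",
   "variable_id": "bathroom_shower",
   "trigger_threshold": 1,
   "penalty_points": 1,
   "note": "placeholder (synthetic)"
  },
  {
   "vulnerability": "visual_disability",
   "variable_id": "natural_light",
   "trigger_threshold": 1,
   "penalty_points": 1,
   "note": "placeholder (synthetic)"
  },
  {
   "vulnerability": "visual_disability",
   "variable_id": "artificial_light",
   "trigger_threshold": 1,
   "penalty_points": 1,
   "note": "placeholder (synthetic)"
  },
  {
   "vulnerability": "visual_disability",
   "variable_id": "stair_safety",
   "trigger_threshold": 1,
   "penalty_points": 1,
   "note": "placeholder (synthetic)"
  },
  {
   "vulnerability": "hearing_disability",
   "variable_id": "fire_safety",
   "trigger_threshold": 1,
   "penalty_points": 1,
   "note": "placeholder (synthetic)"
  }
 ]
}
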