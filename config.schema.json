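{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "oligomorph run configuration",
  "type": "object",
  "properties": {
    "seed": {"type": "integer", "description": "Master seed; recorded in every output."},
    "outdir": {"type": ["string", "null"]},
    "mode": {"enum": ["simulate", "manifest"]},
    "manifest": {
      "type": ["string", "null"],
      "description": "CSV with columns path,group,line,fov,channel (one row per single-channel TIFF); required when mode=manifest."
    },
    "simulation": {
      "type": "object",
      "properties": {
        "n_lines_per_group": {"type": "integer", "minimum": 1},
        "n_fov_per_line": {"type": "integer", "minimum": 1},
        "marker": {"enum": ["MBP", "O4"]},
        "image_shape": {"type": "array", "items": {"type": "integer", "minimum": 64}},
        "n_nuclei": {"type": "integer", "minimum": 0},
        "n_cells": {"type": "integer", "minimum": 0},
        "bleed_coefficient": {"type": "number", "minimum": 0},
        "illumination_amplitude": {"type": "number", "minimum": 0},
        "photon_scale": {"type": "number", "exclusiveMinimum": 0},
        "read_sd": {"type": "number", "minimum": 0},
        "branch_length_effect": {"type": "number", "description": "Multiplicative SCZ shift of true branch length. unstated, chosen"},
        "line_scale_sd": {"type": "number", "minimum": 0}
      }
    },
    "preprocess": {
      "type": "object",
      "properties": {
        "pseudo_flat_field": {"type": "object", "properties": {"blur_radius_px": {"type": ["number", "null"], "description": "null -> image width / 3. unstated, chosen"}}},
        "median_smooth": {"type": "object", "properties": {"radius_px": {"type": "integer", "minimum": 1, "description": "unstated, chosen (2)"}}},
        "subtract_background_paraboloid": {"type": "object", "properties": {"radius_px": {"type": "number", "minimum": 1, "description": "unstated, chosen (50)"}}},
        "enhance_contrast": {"type": "object", "properties": {"saturated_fraction": {"type": "number", "minimum": 0, "exclusiveMaximum": 0.5, "description": "unstated, chosen (0.0035)"}}}
      }
    },
    "segment": {
      "type": "object",
      "properties": {
        "threshold_variant": {
          "type": "object",
          "additionalProperties": {"enum": ["huang", "huang2"]},
          "description": "Published routing: huang2 on DAPI and MBP, huang on O4."
        },
        "binary_ops": {
          "type": "object",
          "additionalProperties": {"type": "array", "items": {"enum": ["erode", "open", "dilate", "close", "watershed"]}},
          "description": "Published routing: DAPI erode/open/dilate/watershed, O4 erode/open."
        },
        "min_area_px": {"type": "integer", "minimum": 1, "description": "unstated, chosen (20)"},
        "solidity_cutoff": {"type": "number", "exclusiveMinimum": 0, "exclusiveMaximum": 1, "description": "Published: ROIs with solidity < 0.7 retained (strict)."},
        "overlap_cutoff": {"type": "number", "exclusiveMinimum": 0, "exclusiveMaximum": 1, "description": "Published: ROIs with < 60% overlap with DAPI ROIs kept (strict; fraction of the marker ROI)."}
      }
    },
    "morphometrics": {
      "type": "object",
      "properties": {
        "methods": {"type": "array", "items": {"enum": ["ridge", "skeleton"]}},
        "sigma": {"type": "number", "exclusiveMinimum": 0, "description": "Ridge scale; >= line width / sqrt(3)."},
        "low_contrast": {"type": "number", "minimum": 0},
        "high_contrast": {"type": "number", "exclusiveMinimum": 0},
        "prune_px": {"type": "number", "minimum": 0, "description": "Spur-branch prune length. unstated, chosen (4)"}
      }
    },
    "stats": {
      "type": "object",
      "properties": {
        "alpha": {"type": "number", "exclusiveMinimum": 0, "exclusiveMaximum": 1, "description": "Published: significance at p < 0.05."},
        "df_method": {"enum": ["between_within", "residual"]},
        "variance_fraction": {"type": "number", "exclusiveMinimum": 0, "maximum": 1},
        "transform": {"type": "boolean", "description": "Select a normalizing transform per metric before testing."}
      }
    },
    "write_overlays": {"type": "boolean"}
  }
}
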