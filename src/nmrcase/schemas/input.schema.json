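{
  "$defs": {
    "AtomRecord": {
      "additionalProperties": false,
      "properties": {
        "element": {
          "enum": [
            "C",
            "N"
          ],
          "title": "Element",
          "type": "string"
        },
        "hybridization": {
          "default": "open",
          "enum": [
            "sp3",
            "sp2",
            "sp",
            "open"
          ],
          "title": "Hybridization",
          "type": "string"
        },
        "id": {
          "title": "Id",
          "type": "string"
        },
        "n_h": {
          "maximum": 4,
          "minimum": 0,
          "title": "N H",
          "type": "integer"
        },
        "shift_ppm": {
          "anyOf": [
            {
              "minimum": 0,
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Shift Ppm"
        }
      },
      "required": [
        "id",
        "element",
        "n_h"
      ],
      "title": "AtomRecord",
      "type": "object"
    },
    "CorrelationLists": {
      "additionalProperties": false,
      "properties": {
        "adequate11": {
          "default": [],
          "items": {
            "maxItems": 2,
            "minItems": 2,
            "prefixItems": [
              {
                "type": "string"
              },
              {
                "type": "string"
              }
            ],
            "type": "array"
          },
          "title": "Adequate11",
          "type": "array"
        },
        "cosy": {
          "default": [],
          "items": {
            "maxItems": 2,
            "minItems": 2,
            "prefixItems": [
              {
                "type": "string"
              },
              {
                "type": "string"
              }
            ],
            "type": "array"
          },
          "title": "Cosy",
          "type": "array"
        },
        "hmbc": {
          "default": [],
          "items": {
            "maxItems": 2,
            "minItems": 2,
            "prefixItems": [
              {
                "type": "string"
              },
              {
                "type": "string"
              }
            ],
            "type": "array"
          },
          "title": "Hmbc",
          "type": "array"
        },
        "n15hmbc": {
          "default": [],
          "items": {
            "maxItems": 2,
            "minItems": 2,
            "prefixItems": [
              {
                "type": "string"
              },
              {
                "type": "string"
              }
            ],
            "type": "array"
          },
          "title": "N15Hmbc",
          "type": "array"
        }
      },
      "title": "CorrelationLists",
      "type": "object"
    },
    "Options": {
      "additionalProperties": false,
      "properties": {
        "allow_4bond_hmbc": {
          "default": false,
          "title": "Allow 4Bond Hmbc",
          "type": "boolean"
        },
        "forbid_heteroatom_heteroatom_bonds": {
          "default": false,
          "title": "Forbid Heteroatom Heteroatom Bonds",
          "type": "boolean"
        },
        "max_results": {
          "default": 1000000,
          "minimum": 1,
          "title": "Max Results",
          "type": "integer"
        },
        "min_ring_size": {
          "default": 3,
          "minimum": 3,
          "title": "Min Ring Size",
          "type": "integer"
        },
        "open_types": {
          "default": false,
          "title": "Open Types",
          "type": "boolean"
        },
        "seed": {
          "default": 0,
          "title": "Seed",
          "type": "integer"
        }
      },
      "title": "Options",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "description": "Top-level NMR input document.",
  "properties": {
    "atoms": {
      "items": {
        "$ref": "#/$defs/AtomRecord"
      },
      "title": "Atoms",
      "type": "array"
    },
    "correlations": {
      "$ref": "#/$defs/CorrelationLists",
      "default": {
        "adequate11": [],
        "cosy": [],
        "hmbc": [],
        "n15hmbc": []
      }
    },
    "formula": {
      "title": "Formula",
      "type": "string"
    },
    "options": {
      "$ref": "#/$defs/Options",
      "default": {
        "allow_4bond_hmbc": false,
        "forbid_heteroatom_heteroatom_bonds": false,
        "max_results": 1000000,
        "min_ring_size": 3,
        "open_types": false,
        "seed": 0
      }
    }
  },
  "required": [
    "formula",
    "atoms"
  ],
  "title": "InputDocument",
  "type": "object"
}
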