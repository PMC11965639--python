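{
  "$defs": {
    "AnnotationSection": {
      "properties": {
        "n_nodes": {
          "title": "N Nodes",
          "type": "integer"
        },
        "n_components": {
          "title": "N Components",
          "type": "integer"
        },
        "tier_counts": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "Tier Counts",
          "type": "object"
        },
        "n_unannotated": {
          "title": "N Unannotated",
          "type": "integer"
        },
        "composition": {
          "items": {
            "maxItems": 3,
            "minItems": 3,
            "prefixItems": [
              {
                "type": "string"
              },
              {
                "type": "integer"
              },
              {
                "type": "number"
              }
            ],
            "type": "array"
          },
          "title": "Composition",
          "type": "array"
        }
      },
      "required": [
        "n_nodes",
        "n_components",
        "tier_counts",
        "n_unannotated",
        "composition"
      ],
      "title": "AnnotationSection",
      "type": "object"
    },
    "CensusSection": {
      "properties": {
        "illumina": {
          "title": "Illumina",
          "type": "integer"
        },
        "minion": {
          "title": "Minion",
          "type": "integer"
        },
        "total_rows": {
          "title": "Total Rows",
          "type": "integer"
        }
      },
      "required": [
        "illumina",
        "minion",
        "total_rows"
      ],
      "title": "CensusSection",
      "type": "object"
    },
    "ComparisonSection": {
      "properties": {
        "cluster_similarity_pct": {
          "title": "Cluster Similarity Pct",
          "type": "integer"
        },
        "orientation": {
          "title": "Orientation",
          "type": "string"
        },
        "rank_corr": {
          "title": "Rank Corr",
          "type": "number"
        },
        "n_hits": {
          "title": "N Hits",
          "type": "integer"
        },
        "unmatched_ref": {
          "items": {
            "type": "string"
          },
          "title": "Unmatched Ref",
          "type": "array"
        }
      },
      "required": [
        "cluster_similarity_pct",
        "orientation",
        "rank_corr",
        "n_hits",
        "unmatched_ref"
      ],
      "title": "ComparisonSection",
      "type": "object"
    },
    "ForwardSection": {
      "properties": {
        "presences": {
          "additionalProperties": {
            "items": {
              "type": "integer"
            },
            "type": "array"
          },
          "title": "Presences",
          "type": "object"
        },
        "classes": {
          "additionalProperties": {
            "items": {
              "type": "string"
            },
            "type": "array"
          },
          "title": "Classes",
          "type": "object"
        },
        "n_distinct_classes": {
          "title": "N Distinct Classes",
          "type": "integer"
        },
        "class_search": {
          "additionalProperties": {
            "maxItems": 2,
            "minItems": 2,
            "prefixItems": [
              {
                "type": "integer"
              },
              {
                "items": {
                  "type": "integer"
                },
                "type": "array"
              }
            ],
            "type": "array"
          },
          "title": "Class Search",
          "type": "object"
        }
      },
      "required": [
        "presences",
        "classes",
        "n_distinct_classes",
        "class_search"
      ],
      "title": "ForwardSection",
      "type": "object"
    },
    "IsomerSection": {
      "properties": {
        "pairs": {
          "items": {
            "maxItems": 2,
            "minItems": 2,
            "prefixItems": [
              {
                "type": "integer"
              },
              {
                "type": "integer"
              }
            ],
            "type": "array"
          },
          "title": "Pairs",
          "type": "array"
        }
      },
      "required": [
        "pairs"
      ],
      "title": "IsomerSection",
      "type": "object"
    },
    "PathwayHit": {
      "properties": {
        "feature_id": {
          "title": "Feature Id",
          "type": "integer"
        },
        "pathway_ids": {
          "items": {
            "type": "string"
          },
          "title": "Pathway Ids",
          "type": "array"
        }
      },
      "required": [
        "feature_id",
        "pathway_ids"
      ],
      "title": "PathwayHit",
      "type": "object"
    },
    "ReverseSection": {
      "properties": {
        "pathway_hits": {
          "items": {
            "$ref": "#/$defs/PathwayHit"
          },
          "title": "Pathway Hits",
          "type": "array"
        },
        "n_pathway_enzymes": {
          "title": "N Pathway Enzymes",
          "type": "integer"
        },
        "n_enzyme_matches": {
          "title": "N Enzyme Matches",
          "type": "integer"
        },
        "matched_by": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "Matched By",
          "type": "object"
        },
        "region_overlap": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "Region Overlap",
          "type": "object"
        },
        "region_ranking": {
          "items": {
            "type": "string"
          },
          "title": "Region Ranking",
          "type": "array"
        },
        "top_region": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "title": "Top Region"
        },
        "neighborhood": {
          "anyOf": [
            {
              "additionalProperties": true,
              "type": "object"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Neighborhood"
        }
      },
      "required": [
        "pathway_hits",
        "n_pathway_enzymes",
        "n_enzyme_matches",
        "matched_by",
        "region_overlap",
        "region_ranking",
        "top_region"
      ],
      "title": "ReverseSection",
      "type": "object"
    }
  },
  "properties": {
    "census": {
      "anyOf": [
        {
          "$ref": "#/$defs/CensusSection"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "comparison": {
      "anyOf": [
        {
          "$ref": "#/$defs/ComparisonSection"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "annotation": {
      "anyOf": [
        {
          "$ref": "#/$defs/AnnotationSection"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "forward": {
      "anyOf": [
        {
          "$ref": "#/$defs/ForwardSection"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "reverse": {
      "anyOf": [
        {
          "$ref": "#/$defs/ReverseSection"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "isomers": {
      "anyOf": [
        {
          "$ref": "#/$defs/IsomerSection"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    }
  },
  "title": "Report",
  "type": "object"
}
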