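{
  "description": "JSON report schema shared by every method.",
  "properties": {
    "d_c": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "title": "D C"
    },
    "effective_k": {
      "title": "Effective K",
      "type": "integer"
    },
    "entropy_bits": {
      "title": "Entropy Bits",
      "type": "number"
    },
    "evaluations": {
      "anyOf": [
        {
          "type": "integer"
        },
        {
          "type": "null"
        }
      ],
      "title": "Evaluations"
    },
    "image_height": {
      "title": "Image Height",
      "type": "integer"
    },
    "image_width": {
      "title": "Image Width",
      "type": "integer"
    },
    "k": {
      "anyOf": [
        {
          "type": "integer"
        },
        {
          "type": "null"
        }
      ],
      "title": "K"
    },
    "method": {
      "title": "Method",
      "type": "string"
    },
    "sec": {
      "title": "Sec",
      "type": "number"
    },
    "seed": {
      "anyOf": [
        {
          "type": "integer"
        },
        {
          "type": "null"
        }
      ],
      "title": "Seed"
    },
    "settings": {
      "additionalProperties": {
        "type": "number"
      },
      "title": "Settings",
      "type": "object"
    },
    "trace": {
      "anyOf": [
        {
          "items": {
            "type": "number"
          },
          "type": "array"
        },
        {
          "type": "null"
        }
      ],
      "title": "Trace"
    }
  },
  "required": [
    "method",
    "seed",
    "d_c",
    "k",
    "effective_k",
    "entropy_bits",
    "sec",
    "evaluations",
    "trace",
    "image_height",
    "image_width",
    "settings"
  ],
  "title": "SegmentationReport",
  "type": "object"
}
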