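{
 "$defs": {
  "BoundaryDoc": {
   "additionalProperties": true,
   "properties": {
    "x0": {
     "default": "absorb",
     "enum": [
      "absorb",
      "fresnel",
      "mirror",
      "cyclic"
     ],
     "title": "X0",
     "type": "string"
    },
    "x1": {
     "default": "absorb",
     "enum": [
      "absorb",
      "fresnel",
      "mirror",
      "cyclic"
     ],
     "title": "X1",
     "type": "string"
    },
    "y0": {
     "default": "absorb",
     "enum": [
      "absorb",
      "fresnel",
      "mirror",
      "cyclic"
     ],
     "title": "Y0",
     "type": "string"
    },
    "y1": {
     "default": "absorb",
     "enum": [
      "absorb",
      "fresnel",
      "mirror",
      "cyclic"
     ],
     "title": "Y1",
     "type": "string"
    },
    "z0": {
     "default": "absorb",
     "enum": [
      "absorb",
      "fresnel",
      "mirror",
      "cyclic"
     ],
     "title": "Z0",
     "type": "string"
    },
    "z1": {
     "default": "absorb",
     "enum": [
      "absorb",
      "fresnel",
      "mirror",
      "cyclic"
     ],
     "title": "Z1",
     "type": "string"
    }
   },
   "title": "BoundaryDoc",
   "type": "object"
  },
  "DetectorDoc": {
   "additionalProperties": true,
   "properties": {
    "Pos": {
     "maxItems": 3,
     "minItems": 3,
     "prefixItems": [
      {
       "type": "number"
      },
      {
       "type": "number"
      },
      {
       "type": "number"
      }
     ],
     "title": "Pos",
     "type": "array"
    },
    "R": {
     "exclusiveMinimum": 0.0,
     "title": "R",
     "type": "number"
    }
   },
   "required": [
    "Pos",
    "R"
   ],
   "title": "DetectorDoc",
   "type": "object"
  },
  "DomainDoc": {
   "additionalProperties": true,
   "properties": {
    "Boundary": {
     "$ref": "#/$defs/BoundaryDoc"
    },
    "Dim": {
     "maxItems": 3,
     "minItems": 3,
     "prefixItems": [
      {
       "type": "integer"
      },
      {
       "type": "integer"
      },
      {
       "type": "integer"
      }
     ],
     "title": "Dim",
     "type": "array"
    },
    "LengthUnit": {
     "default": 1.0,
     "exclusiveMinimum": 0.0,
     "title": "Lengthunit",
     "type": "number"
    },
    "Media": {
     "items": {
      "$ref": "#/$defs/MediumDoc"
     },
     "minItems": 1,
     "title": "Media",
     "type": "array"
    },
    "MediaFormat": {
     "default": "labels",
     "enum": [
      "labels",
      "muamus_float"
     ],
     "title": "Mediaformat",
     "type": "string"
    },
    "Volume": {
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
     "title": "Volume"
    }
   },
   "required": [
    "Dim",
    "Media"
   ],
   "title": "DomainDoc",
   "type": "object"
  },
  "ForwardDoc": {
   "additionalProperties": true,
   "properties": {
    "Dt": {
     "exclusiveMinimum": 0.0,
     "title": "Dt",
     "type": "number"
    },
    "T0": {
     "default": 0.0,
     "minimum": 0.0,
     "title": "T0",
     "type": "number"
    },
    "T1": {
     "title": "T1",
     "type": "number"
    }
   },
   "required": [
    "T1",
    "Dt"
   ],
   "title": "ForwardDoc",
   "type": "object"
  },
  "MediumDoc": {
   "additionalProperties": true,
   "properties": {
    "g": {
     "maximum": 1.0,
     "minimum": -1.0,
     "title": "G",
     "type": "number"
    },
    "mua": {
     "minimum": 0.0,
     "title": "Mua",
     "type": "number"
    },
    "mus": {
     "minimum": 0.0,
     "title": "Mus",
     "type": "number"
    },
    "n": {
     "minimum": 1.0,
     "title": "N",
     "type": "number"
    }
   },
   "required": [
    "mua",
    "mus",
    "g",
    "n"
   ],
   "title": "MediumDoc",
   "type": "object"
  },
  "OptodeDoc": {
   "additionalProperties": true,
   "properties": {
    "Detector": {
     "items": {
      "$ref": "#/$defs/DetectorDoc"
     },
     "title": "Detector",
     "type": "array"
    },
    "Source": {
     "$ref": "#/$defs/SourceDoc"
    }
   },
   "required": [
    "Source"
   ],
   "title": "OptodeDoc",
   "type": "object"
  },
  "SessionDoc": {
   "additionalProperties": true,
   "properties": {
    "DoMismatch": {
     "default": false,
     "title": "Domismatch",
     "type": "boolean"
    },
    "DoNormalize": {
     "default": true,
     "title": "Donormalize",
     "type": "boolean"
    },
    "ID": {
     "default": "mcvox",
     "title": "Id",
     "type": "string"
    },
    "OutputType": {
     "default": "single",
     "enum": [
      "single",
      "double"
     ],
     "title": "Outputtype",
     "type": "string"
    },
    "Photons": {
     "default": 100000,
     "minimum": 1,
     "title": "Photons",
     "type": "integer"
    },
    "RNGSeed": {
     "default": 1,
     "minimum": 0,
     "title": "Rngseed",
     "type": "integer"
    }
   },
   "title": "SessionDoc",
   "type": "object"
  },
  "SourceDoc": {
   "additionalProperties": true,
   "properties": {
    "Dir": {
     "default": [
      0.0,
      0.0,
      1.0
     ],
     "maxItems": 3,
     "minItems": 3,
     "prefixItems": [
      {
       "type": "number"
      },
      {
       "type": "number"
      },
      {
       "type": "number"
      }
     ],
     "title": "Dir",
     "type": "array"
    },
    "Focus": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Focus"
    },
    "Param1": {
     "default": [
      0.0,
      0.0,
      0.0,
      0.0
     ],
     "maxItems": 4,
     "minItems": 4,
     "prefixItems": [
      {
       "type": "number"
      },
      {
       "type": "number"
      },
      {
       "type": "number"
      },
      {
       "type": "number"
      }
     ],
     "title": "Param1",
     "type": "array"
    },
    "Param2": {
     "default": [
      0.0,
      0.0,
      0.0,
      0.0
     ],
     "maxItems": 4,
     "minItems": 4,
     "prefixItems": [
      {
       "type": "number"
      },
      {
       "type": "number"
      },
      {
       "type": "number"
      },
      {
       "type": "number"
      }
     ],
     "title": "Param2",
     "type": "array"
    },
    "Pattern": {
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
     "title": "Pattern"
    },
    "Phase": {
     "default": 0.0,
     "title": "Phase",
     "type": "number"
    },
    "Pos": {
     "maxItems": 3,
     "minItems": 3,
     "prefixItems": [
      {
       "type": "number"
      },
      {
       "type": "number"
      },
      {
       "type": "number"
      }
     ],
     "title": "Pos",
     "type": "array"
    },
    "Type": {
     "enum": [
      "pencil",
      "isotropic",
      "cone",
      "planar",
      "disk",
      "gaussian",
      "fourier",
      "line",
      "slit",
      "pattern",
      "pattern3d"
     ],
     "title": "Type",
     "type": "string"
    }
   },
   "required": [
    "Type",
    "Pos"
   ],
   "title": "SourceDoc",
   "type": "object"
  }
 },
 "additionalProperties": true,
 "description": "Top-level simulation input document.",
 "properties": {
  "Domain": {
   "$ref": "#/$defs/DomainDoc"
  },
  "Forward": {
   "$ref": "#/$defs/ForwardDoc"
  },
  "Optode": {
   "$ref": "#/$defs/OptodeDoc"
  },
  "Session": {
   "$ref": "#/$defs/SessionDoc"
  },
  "Shapes": {
   "anyOf": [
    {
     "items": {
      "additionalProperties": true,
      "type": "object"
     },
     "type": "array"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Shapes"
  }
 },
 "required": [
  "Forward",
  "Optode",
  "Domain"
 ],
 "title": "InputDoc",
 "type": "object"
}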