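{
  "description": "AQ-50 scoring key: per-item autistic-characteristic pole and subscale assignment (published instrument; editable).",
  "agree_scored": [2, 4, 5, 6, 7, 9, 12, 13, 16, 18, 19, 20, 21, 22, 23, 26,
                   33, 35, 39, 41, 42, 43, 45, 46],
  "subscales": {
    "social skills": [1, 11, 13, 15, 22, 36, 44, 45, 47, 48],
    "attention switching": [2, 4, 10, 16, 25, 32, 34, 37, 43, 46],
    "attention to detail": [5, 6, 9, 12, 19, 23, 28, 29, 30, 49],
    "communication": [7, 17, 18, 26, 27, 31, 33, 35, 38, 39],
    "imagination": [3, 8, 14, 20, 21, 24, 40, 41, 42, 50]
  }
}
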