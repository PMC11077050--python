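{
  "regions": [
    {
      "id": "0",
      "start": 6,
      "end": 7,
      "motif": "B"
    },
    {
      "id": "I",
      "start": 8,
      "end": 11,
      "motif": "A"
    },
    {
      "id": "IV",
      "start": 13,
      "end": 16,
      "motif": "C"
    },
    {
      "id": "II",
      "start": 19,
      "end": 23,
      "motif": "A"
    },
    {
      "id": "V",
      "start": 25,
      "end": 29,
      "motif": "C"
    },
    {
      "id": "III",
      "start": 31,
      "end": 37,
      "motif": "B"
    }
  ]
}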