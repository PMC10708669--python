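{
  "boxes": [
    {
      "box_id": 1,
      "phases": [
        {"mode": "LD", "from": "2024-01-01 07:00", "on": "07:00", "off": "19:00", "T": 24.7}
      ]
    },
    {
      "box_id": 2,
      "phases": [
        {"mode": "LD", "from": "2024-01-01 07:00", "on": "04:00", "off": "20:00", "T": 24.7}
      ]
    },
    {
      "box_id": 3,
      "phases": [
        {"mode": "LD", "from": "2024-01-01 07:00", "on": "08:00", "off": "16:00", "T": 24.7}
      ]
    },
    {
      "box_id": 4,
      "phases": [
        {"mode": "LD", "from": "2024-01-01 07:00", "on": "07:00", "off": "19:00", "T": 25.0}
      ]
    },
    {
      "box_id": 5,
      "phases": [
        {"mode": "DD", "from": "2024-01-01 07:00", "T": 24.0}
      ]
    }
  ]
}
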