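{
  "boxes": [
    {
      "box_id": 1,
      "phases": [
        {"mode": "LD", "from": "2024-01-01 07:00", "on": "07:00", "off": "19:00", "T": 24.0},
        {"mode": "DD", "from": "2024-01-15 07:00", "T": 24.0},
        {"mode": "LD", "from": "2024-02-05 07:00", "on": "07:00", "off": "19:00", "T": 24.0},
        {"mode": "LD", "from": "2024-02-19 01:00", "on": "01:00", "off": "13:00", "T": 24.0}
      ]
    },
    {
      "box_id": 2,
      "phases": [
        {"mode": "LD", "from": "2024-01-01 07:00", "on": "07:00", "off": "19:00", "T": 24.0},
        {"mode": "DD", "from": "2024-01-15 07:00", "T": 24.0},
        {"mode": "LD", "from": "2024-02-05 07:00", "on": "07:00", "off": "19:00", "T": 24.0},
        {"mode": "LD", "from": "2024-02-19 01:00", "on": "01:00", "off": "13:00", "T": 24.0}
      ]
    },
    {
      "box_id": 3,
      "phases": [
        {"mode": "LD", "from": "2024-01-01 07:00", "on": "07:00", "off": "19:00", "T": 24.0},
        {"mode": "DD", "from": "2024-01-15 07:00", "T": 24.0},
        {"mode": "LD", "from": "2024-02-05 07:00", "on": "07:00", "off": "19:00", "T": 24.0},
        {"mode": "LD", "from": "2024-02-19 01:00", "on": "01:00", "off": "13:00", "T": 24.0}
      ]
    },
    {
      "box_id": 4,
      "phases": [
        {"mode": "LD", "from": "2024-01-01 07:00", "on": "07:00", "off": "19:00", "T": 24.0},
        {"mode": "DD", "from": "2024-01-15 07:00", "T": 24.0},
        {"mode": "LD", "from": "2024-02-05 07:00", "on": "07:00", "off": "19:00", "T": 24.0},
        {"mode": "LD", "from": "2024-02-19 01:00", "on": "01:00", "off": "13:00", "T": 24.0}
      ]
    },
    {
      "box_id": 5,
      "phases": [
        {"mode": "LD", "from": "2024-01-01 07:00", "on": "07:00", "off": "19:00", "T": 24.0},
        {"mode": "DD", "from": "2024-01-15 07:00", "T": 24.0},
        {"mode": "LD", "from": "2024-02-05 07:00", "on": "07:00", "off": "19:00", "T": 24.0},
        {"mode": "LD", "from": "2024-02-19 01:00", "on": "01:00", "off": "13:00", "T": 24.0}
      ]
    }
  ]
}
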