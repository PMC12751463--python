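{
  "edges": [
    {
      "from": "ecg",
      "p": 1.0,
      "provenance": "trivial",
      "to": "g"
    },
    {
      "from": "g",
      "p": 0.27,
      "provenance": "ai_threshold",
      "to": "h"
    },
    {
      "from": "g",
      "p": 0.73,
      "provenance": "ai_threshold",
      "to": "k"
    },
    {
      "from": "k",
      "p": 1.0,
      "provenance": "trivial",
      "to": "kx"
    },
    {
      "from": "h",
      "p": 1.0,
      "provenance": "trivial",
      "to": "consult"
    },
    {
      "from": "consult",
      "p": 1.0,
      "to": "j"
    },
    {
      "from": "j",
      "p": 0.74,
      "provenance": "ai_precision",
      "to": "l"
    },
    {
      "from": "j",
      "p": 0.26,
      "provenance": "ai_precision",
      "to": "m"
    },
    {
      "from": "l",
      "p": 1.0,
      "provenance": "trivial",
      "to": "o"
    },
    {
      "from": "m",
      "p": 1.0,
      "provenance": "trivial",
      "to": "p"
    }
  ],
  "nodes": [
    {
      "cost": 174.28,
      "id": "consult",
      "kind": "decision",
      "name": "Cardiologist orders echo",
      "turnaround_weeks": 4.0
    },
    {
      "cost": 708.0,
      "id": "ecg",
      "kind": "action",
      "name": "ECG"
    },
    {
      "ai": true,
      "id": "g",
      "kind": "action",
      "name": "AI reads ECG"
    },
    {
      "ai": true,
      "id": "h",
      "kind": "result",
      "name": "Predicted SHD",
      "result_value": 1
    },
    {
      "cost": 1852.0,
      "id": "j",
      "kind": "action",
      "name": "Echocardiography",
      "turnaround_weeks": 2.0
    },
    {
      "ai": true,
      "id": "k",
      "kind": "result",
      "name": "Predict no SHD",
      "result_value": 0
    },
    {
      "id": "kx",
      "kind": "exit",
      "name": "Process concludes"
    },
    {
      "id": "l",
      "kind": "result",
      "name": "SHD confirmed",
      "result_value": 1
    },
    {
      "id": "m",
      "kind": "result",
      "name": "No SHD",
      "result_value": 0
    },
    {
      "id": "o",
      "kind": "exit",
      "name": "Confirmed SHD"
    },
    {
      "id": "p",
      "kind": "exit",
      "name": "SHD ruled out"
    }
  ],
  "root": "ecg"
}
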