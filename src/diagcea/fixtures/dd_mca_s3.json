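{
  "edges": [
    {
      "from": "1",
      "p": 1.0,
      "provenance": "trivial",
      "to": "2"
    },
    {
      "from": "2",
      "p": 1.0,
      "to": "3"
    },
    {
      "from": "3",
      "p": 0.10026041666666667,
      "provenance": "yield",
      "to": "5"
    },
    {
      "from": "3",
      "p": 0.8997395833333334,
      "provenance": "yield",
      "to": "6"
    },
    {
      "from": "5",
      "p": 1.0,
      "provenance": "trivial",
      "to": "5x"
    },
    {
      "from": "6",
      "p": 1.0,
      "provenance": "trivial",
      "to": "10"
    },
    {
      "from": "10",
      "p": 1.0,
      "to": "13"
    },
    {
      "from": "13",
      "p": 0.35,
      "provenance": "yield",
      "to": "15"
    },
    {
      "from": "13",
      "p": 0.65,
      "provenance": "yield",
      "to": "16"
    },
    {
      "from": "15",
      "p": 1.0,
      "provenance": "trivial",
      "to": "15x"
    },
    {
      "from": "16",
      "p": 1.0,
      "provenance": "trivial",
      "to": "16x"
    }
  ],
  "nodes": [
    {
      "id": "1",
      "kind": "action",
      "name": "Diagnostic initiation"
    },
    {
      "cost": 174.28,
      "id": "10",
      "kind": "decision",
      "name": "Decision 2",
      "turnaround_weeks": 4.0
    },
    {
      "cost": 4847.47,
      "id": "13",
      "kind": "action",
      "name": "ES (second tier)",
      "turnaround_weeks": 8.0
    },
    {
      "id": "15",
      "kind": "result",
      "name": "ES (second tier) positive",
      "result_value": 1
    },
    {
      "id": "15x",
      "kind": "exit"
    },
    {
      "id": "16",
      "kind": "result",
      "name": "ES (second tier) negative",
      "result_value": 0
    },
    {
      "id": "16x",
      "kind": "exit"
    },
    {
      "cost": 174.28,
      "id": "2",
      "kind": "decision",
      "name": "Decision 1",
      "turnaround_weeks": 4.0
    },
    {
      "cost": 871.39,
      "id": "3",
      "kind": "action",
      "name": "CMA",
      "turnaround_weeks": 2.0
    },
    {
      "id": "5",
      "kind": "result",
      "name": "CMA positive",
      "result_value": 1
    },
    {
      "id": "5x",
      "kind": "exit",
      "name": "Diagnosed by CMA"
    },
    {
      "id": "6",
      "kind": "result",
      "name": "CMA negative",
      "result_value": 0
    }
  ],
  "root": "1"
}
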