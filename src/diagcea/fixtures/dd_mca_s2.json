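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
      "to": "14"
    },
    {
      "from": "14",
      "p": 0.21238938053097345,
      "provenance": "yield",
      "to": "17"
    },
    {
      "from": "14",
      "p": 0.7876106194690266,
      "provenance": "yield",
      "to": "18"
    },
    {
      "from": "17",
      "p": 1.0,
      "provenance": "trivial",
      "to": "17x"
    },
    {
      "from": "18",
      "p": 1.0,
      "provenance": "trivial",
      "to": "22"
    },
    {
      "from": "22",
      "p": 1.0,
      "to": "24"
    },
    {
      "from": "24",
      "p": 0.32947976878612717,
      "provenance": "yield",
      "to": "25"
    },
    {
      "from": "24",
      "p": 0.6705202312138728,
      "provenance": "yield",
      "to": "26"
    },
    {
      "from": "25",
      "p": 1.0,
      "provenance": "trivial",
      "to": "25x"
    },
    {
      "from": "26",
      "p": 1.0,
      "provenance": "trivial",
      "to": "26x"
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
      "cost": 1600.0,
      "id": "14",
      "kind": "action",
      "name": "Gene panel",
      "turnaround_weeks": 4.0
    },
    {
      "id": "17",
      "kind": "result",
      "name": "GP positive",
      "result_value": 1
    },
    {
      "id": "17x",
      "kind": "exit",
      "name": "Diagnosed by GP"
    },
    {
      "id": "18",
      "kind": "result",
      "name": "GP negative",
      "result_value": 0
    },
    {
      "cost": 174.28,
      "id": "2",
      "kind": "decision",
      "name": "Decision 1",
      "turnaround_weeks": 4.0
    },
    {
      "cost": 174.28,
      "id": "22",
      "kind": "decision",
      "name": "Decision 3",
      "turnaround_weeks": 4.0
    },
    {
      "cost": 4847.47,
      "id": "24",
      "kind": "action",
      "name": "ES (third tier)",
      "turnaround_weeks": 8.0
    },
    {
      "id": "25",
      "kind": "result",
      "name": "ES (third tier) positive",
      "result_value": 1
    },
    {
      "id": "25x",
      "kind": "exit"
    },
    {
      "id": "26",
      "kind": "result",
      "name": "ES (third tier) negative",
      "result_value": 0
    },
    {
      "id": "26x",
      "kind": "exit"
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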