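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
      "to": "1'"
    },
    {
      "from": "1'",
      "p": 1.0,
      "provenance": "ai_threshold",
      "to": "2'"
    },
    {
      "from": "1'",
      "p": 0.0,
      "provenance": "ai_threshold",
      "to": "3'"
    },
    {
      "from": "2'",
      "p": 1.0,
      "provenance": "trivial",
      "to": "4'"
    },
    {
      "from": "4'",
      "p": 0.87,
      "provenance": "ai_precision",
      "to": "5'"
    },
    {
      "from": "4'",
      "p": 0.13,
      "provenance": "ai_precision",
      "to": "6'"
    },
    {
      "from": "5'",
      "p": 1.0,
      "provenance": "trivial",
      "to": "5'x"
    },
    {
      "from": "6'",
      "p": 1.0,
      "provenance": "trivial",
      "to": "8'"
    },
    {
      "from": "8'",
      "p": 0.32947976878612717,
      "provenance": "yield",
      "to": "9'"
    },
    {
      "from": "8'",
      "p": 0.6705202312138728,
      "provenance": "yield",
      "to": "10'"
    },
    {
      "from": "9'",
      "p": 1.0,
      "provenance": "trivial",
      "to": "9'x"
    },
    {
      "from": "10'",
      "p": 1.0,
      "provenance": "trivial",
      "to": "10'x"
    },
    {
      "from": "3'",
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
      "ai": true,
      "id": "1'",
      "kind": "action",
      "name": "AI predicts GP yield"
    },
    {
      "cost": 174.28,
      "id": "10",
      "kind": "decision",
      "name": "Decision 2 (expert fallback)",
      "turnaround_weeks": 4.0
    },
    {
      "id": "10'",
      "kind": "result",
      "name": "ES (third tier, auto) negative",
      "result_value": 0
    },
    {
      "id": "10'x",
      "kind": "exit"
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
      "ai": true,
      "id": "2'",
      "kind": "result",
      "name": "r >= r*",
      "result_value": 1
    },
    {
      "cost": 871.39,
      "id": "3",
      "kind": "action",
      "name": "CMA",
      "turnaround_weeks": 2.0
    },
    {
      "ai": true,
      "id": "3'",
      "kind": "result",
      "name": "r < r*",
      "result_value": 0
    },
    {
      "cost": 1600.0,
      "id": "4'",
      "kind": "action",
      "name": "Gene panel (auto-ordered)",
      "turnaround_weeks": 4.0
    },
    {
      "id": "5",
      "kind": "result",
      "name": "CMA positive",
      "result_value": 1
    },
    {
      "id": "5'",
      "kind": "result",
      "name": "GP positive",
      "result_value": 1
    },
    {
      "id": "5'x",
      "kind": "exit",
      "name": "Diagnosed by GP"
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
    },
    {
      "id": "6'",
      "kind": "result",
      "name": "GP negative",
      "result_value": 0
    },
    {
      "cost": 4847.47,
      "id": "8'",
      "kind": "action",
      "name": "ES (third tier, auto)",
      "turnaround_weeks": 8.0
    },
    {
      "id": "9'",
      "kind": "result",
      "name": "ES (third tier, auto) positive",
      "result_value": 1
    },
    {
      "id": "9'x",
      "kind": "exit"
    }
  ],
  "root": "1"
}
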