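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
      "to": "4"
    },
    {
      "from": "4",
      "p": 0.3698630136986301,
      "provenance": "yield",
      "to": "7"
    },
    {
      "from": "4",
      "p": 0.6301369863013699,
      "provenance": "yield",
      "to": "8"
    },
    {
      "from": "7",
      "p": 1.0,
      "provenance": "trivial",
      "to": "7x"
    },
    {
      "from": "8",
      "p": 1.0,
      "provenance": "trivial",
      "to": "8x"
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
      "id": "2",
      "kind": "decision",
      "name": "Decision 1",
      "turnaround_weeks": 4.0
    },
    {
      "cost": 4847.47,
      "id": "4",
      "kind": "action",
      "name": "ES (first tier)",
      "turnaround_weeks": 8.0
    },
    {
      "id": "7",
      "kind": "result",
      "name": "ES (first tier) positive",
      "result_value": 1
    },
    {
      "id": "7x",
      "kind": "exit"
    },
    {
      "id": "8",
      "kind": "result",
      "name": "ES (first tier) negative",
      "result_value": 0
    },
    {
      "id": "8x",
      "kind": "exit"
    }
  ],
  "root": "1"
}
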