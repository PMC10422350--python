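{
  "description": "Reference 3x3 signature matrices (rows = ECG zones, columns = sound zones) for two subjects across breathing conditions, stored verbatim as regression fixtures. Element sums fall slightly below 1 (about 0.9895).",
  "entries": [
    {
      "name": "1000mL_subject1",
      "subject": 1,
      "condition": "1000mL",
      "kind": "target",
      "values": [[0.0, 0.0, 0.2421], [0.0, 0.5263, 0.0], [0.2211, 0.0, 0.0]]
    },
    {
      "name": "500mL_subject1",
      "subject": 1,
      "condition": "500mL",
      "kind": "target",
      "values": [[0.0, 0.0, 0.0], [0.0, 0.7053, 0.0], [0.2842, 0.0, 0.0]]
    },
    {
      "name": "cough_subject1",
      "subject": 1,
      "condition": "cough",
      "kind": "target",
      "values": [[0.0, 0.0, 0.9053], [0.0, 0.0105, 0.0737], [0.0, 0.0, 0.0]]
    },
    {
      "name": "1000mL_subject2",
      "subject": 2,
      "condition": "1000mL",
      "kind": "target",
      "values": [[0.0, 0.0211, 0.3474], [0.0, 0.2421, 0.0], [0.1474, 0.2316, 0.0]]
    },
    {
      "name": "500mL_subject2",
      "subject": 2,
      "condition": "500mL",
      "kind": "target",
      "values": [[0.0, 0.0, 0.0], [0.0, 0.5158, 0.0], [0.4, 0.0737, 0.0]]
    },
    {
      "name": "template_subject1",
      "subject": 1,
      "condition": "template",
      "kind": "template",
      "values": [[0.0, 0.0631, 0.0807], [0.0035, 0.5438, 0.0631], [0.2281, 0.007, 0.0]]
    },
    {
      "name": "template_subject2",
      "subject": 2,
      "condition": "template",
      "kind": "template",
      "values": [[0.0, 0.0105, 0.4105], [0.0, 0.2211, 0.0], [0.1474, 0.2, 0.0]]
    }
  ]
}
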