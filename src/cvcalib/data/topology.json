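{
  "name": "reduced-closed-loop-cvs",
  "description": "Closed-loop lumped-parameter circulation: four heart chambers, four valves, pulmonary artery/vein, aortic root with upper-body/cerebral/descending branches, seven terminal beds, and upper/lower venous return.",
  "compartments": [
    {"name": "RA", "kind": "chamber", "label": "right atrium"},
    {"name": "RV", "kind": "chamber", "label": "right ventricle"},
    {"name": "LA", "kind": "chamber", "label": "left atrium"},
    {"name": "LV", "kind": "chamber", "label": "left ventricle"},
    {"name": "trv", "kind": "valve", "label": "tricuspid valve"},
    {"name": "puv", "kind": "valve", "label": "pulmonary valve"},
    {"name": "miv", "kind": "valve", "label": "mitral valve"},
    {"name": "aov", "kind": "valve", "label": "aortic valve"},
    {"name": "par", "kind": "vessel", "label": "pulmonary artery"},
    {"name": "pvn", "kind": "vessel", "label": "pulmonary vein"},
    {"name": "aor", "kind": "vessel", "label": "aortic root"},
    {"name": "ubr", "kind": "vessel", "label": "upper-body arterial branch"},
    {"name": "cer", "kind": "vessel", "label": "cerebral arterial branch"},
    {"name": "mca", "kind": "vessel", "label": "middle cerebral artery"},
    {"name": "bra", "kind": "vessel", "label": "brachial artery"},
    {"name": "dao", "kind": "vessel", "label": "descending aorta"},
    {"name": "LE_T", "kind": "terminal", "label": "leg terminal bed"},
    {"name": "BR_T", "kind": "terminal", "label": "brachial terminal bed"},
    {"name": "AC_T", "kind": "terminal", "label": "anterior cerebral terminal bed"},
    {"name": "EC_T", "kind": "terminal", "label": "external carotid terminal bed"},
    {"name": "MC_T", "kind": "terminal", "label": "middle cerebral terminal bed"},
    {"name": "PC_T", "kind": "terminal", "label": "posterior cerebral terminal bed"},
    {"name": "TR_T", "kind": "terminal", "label": "trunk terminal bed"},
    {"name": "vub", "kind": "vein", "label": "venous upper body"},
    {"name": "svc", "kind": "conduit", "label": "superior vena cava"},
    {"name": "vlb", "kind": "vein", "label": "venous lower body"},
    {"name": "ivc", "kind": "conduit", "label": "inferior vena cava"}
  ],
  "connections": [
    ["RA", "trv"], ["trv", "RV"], ["RV", "puv"], ["puv", "par"],
    ["par", "pvn"], ["pvn", "LA"], ["LA", "miv"], ["miv", "LV"],
    ["LV", "aov"], ["aov", "aor"],
    ["aor", "ubr"], ["aor", "dao"],
    ["ubr", "cer"], ["ubr", "bra"],
    ["cer", "mca"],
    ["cer", "AC_T"], ["cer", "EC_T"], ["cer", "PC_T"],
    ["mca", "MC_T"],
    ["bra", "BR_T"],
    ["dao", "LE_T"], ["dao", "TR_T"],
    ["AC_T", "vub"], ["EC_T", "vub"], ["PC_T", "vub"],
    ["MC_T", "vub"], ["BR_T", "vub"],
    ["LE_T", "vlb"], ["TR_T", "vlb"],
    ["vub", "svc"], ["svc", "RA"],
    ["vlb", "ivc"], ["ivc", "RA"]
  ]
}
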