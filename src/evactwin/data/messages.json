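[
  {
    "id": "C1",
    "category": "control",
    "text": "A hurricane watch is currently in effect for your area. Stay tuned to local updates."
  },
  {
    "id": "F1",
    "category": "fear",
    "text": "A hurricane watch is currently in effect for your area. Stay tuned to local updates. Storm surge will flood entire neighborhoods within hours. If you stay, emergency services may not be able to reach you."
  },
  {
    "id": "F2",
    "category": "fear",
    "text": "A hurricane watch is currently in effect for your area. Stay tuned to local updates. This hurricane is stronger than Hurricane Andrew, a Category 5 hurricane. Many lives were lost when people ignored evacuation orders—do not let history repeat itself."
  },
  {
    "id": "F3",
    "category": "fear",
    "text": "A hurricane watch is currently in effect for your area. Stay tuned to local updates. If you stay behind, you are risking your life and the lives of your children. This storm is deadly."
  },
  {
    "id": "E1",
    "category": "efficacy",
    "text": "A hurricane watch is currently in effect for your area. Stay tuned to local updates. You can protect your family—evacuate now and head to the designated shelters. They are stocked and ready."
  },
  {
    "id": "E2",
    "category": "efficacy",
    "text": "A hurricane watch is currently in effect for your area. Stay tuned to local updates. Evacuation routes are open and free. Police and emergency personnel are standing by to help you get out safely."
  },
  {
    "id": "E3",
    "category": "efficacy",
    "text": "A hurricane watch is currently in effect for your area. Stay tuned to local updates. We’ve prepared shelters with food, power, and space for families and pets. You’re not alone—we have got you."
  },
  {
    "id": "M1",
    "category": "fear_efficacy",
    "text": "A hurricane watch is currently in effect for your area. Stay tuned to local updates. This storm is deadly—but you can survive it by evacuating now. Shelters are ready and transportation is available."
  },
  {
    "id": "M2",
    "category": "fear_efficacy",
    "text": "A hurricane watch is currently in effect for your area. Stay tuned to local updates. Ignoring this storm could cost lives. But acting now can protect your loved ones—follow the evacuation guidance."
  },
  {
    "id": "M3",
    "category": "fear_efficacy",
    "text": "A hurricane watch is currently in effect for your area. Stay tuned to local updates. The danger is real, but so is your ability to act. Leave now, and you’ll be safe in a designated shelter."
  },
  {
    "id": "T1",
    "category": "norm",
    "text": "A hurricane watch is currently in effect for your area. Stay tuned to local updates. Evacuation helps protect what matters most—your family and your home. Most of your community have already started evacuating the area. There are emergency personnel ready to assist you."
  },
  {
    "id": "T2",
    "category": "norm",
    "text": "A hurricane watch is currently in effect for your area. Stay tuned to local updates. Your neighbors are evacuating. Join them and stay safe."
  },
  {
    "id": "T3",
    "category": "norm",
    "text": "A hurricane watch is currently in effect for your area. Stay tuned to local updates. Do not be the last to evacuate. Everyone else is leaving."
  },
  {
    "id": "FEN1",
    "category": "fear_efficacy_norm",
    "text": "A hurricane watch is currently in effect for your area. Stay tuned to local updates. Staying behind could put you and your family in serious danger, floodwaters are expected to rise quickly. Most of your neighbors have already left for shelters, which are open and fully stocked. Join them now and keep your family safe."
  },
  {
    "id": "FEN2",
    "category": "fear_efficacy_norm",
    "text": "A hurricane watch is currently in effect for your area. Stay tuned to local updates. This storm is unlike anything we have seen in years. Do not wait until it’s too late, evacuation routes are clear, and emergency teams are ready to help. Your community is counting on everyone to act quickly."
  },
  {
    "id": "FEN3",
    "category": "fear_efficacy_norm",
    "text": "A hurricane watch is currently in effect for your area. Stay tuned to local updates. If you remain home, emergency responders may not be able to reach you during the worst of the storm. Most people in your area are already on their way to safety. Protect yourself and your loved ones by heading to the nearest shelter now."
  }
]
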