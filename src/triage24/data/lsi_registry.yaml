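# Default life-saving-intervention (LSI) vocabulary.
#
# Ground truth: a casualty is Priority One iff they received >= 1 intervention
# from this list.  This default is a RECONSTRUCTION of the published
# consensus-derived list of life-saving interventions (expert consensus on
# major-incident management); it is shipped as editable configuration because
# trauma registries encode interventions under local coding schemes — replace
# or extend this file to match your registry's codes.  Matching is by exact
# code string.
#
# The sentinel code "lsi_sentinel" is appended by the synthetic-cohort
# generator to mark generated true-P1 casualties, so that the ground-truth
# pathway (intervention-set intersection) is exercised end to end.
interventions:
  intubation: "Endotracheal intubation"
  surgical_airway: "Surgical airway (cricothyroidotomy)"
  airway_adjunct_obstruction: "Airway repositioning/adjunct for actual obstruction"
  needle_thoracocentesis: "Needle thoracocentesis for tension pneumothorax"
  tube_thoracostomy: "Tube thoracostomy (chest drain)"
  assisted_ventilation: "Positive-pressure / assisted ventilation"
  tourniquet: "Tourniquet applied for catastrophic limb haemorrhage"
  haemostatic_dressing: "Haemostatic dressing / direct pressure for catastrophic haemorrhage"
  pelvic_binder: "Pelvic binder for unstable pelvic injury with shock"
  blood_transfusion: "Transfusion of blood products for hypovolaemic shock"
  massive_transfusion: "Massive transfusion (>= 4 units in first hour)"
  laparotomy_haemorrhage: "Emergency laparotomy for haemorrhage control"
  thoracotomy: "Thoracotomy (resuscitative or for haemorrhage control)"
  vascular_surgery_haemorrhage: "Surgical/interventional control of vascular haemorrhage"
  emergency_amputation: "Emergency amputation for entrapment/haemorrhage"
  pericardiocentesis: "Pericardiocentesis / relief of cardiac tamponade"
  acls_arrest: "ACLS for cardiac arrest"
  defibrillation: "Defibrillation"
  decompressive_craniectomy: "Emergency craniotomy/craniectomy for intracranial haemorrhage"
  seizure_termination: "Pharmacological termination of status epilepticus"
  chest_escharotomy: "Chest escharotomy for ventilatory compromise"
  lsi_sentinel: "Synthetic-cohort sentinel LSI (generated true-P1 marker)"
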