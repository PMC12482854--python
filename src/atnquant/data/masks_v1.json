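{
 "whole_cerebellum": [
  "Left Cerebellum Exterior",
  "Right Cerebellum Exterior",
  "Left Cerebellum White Matter",
  "Right Cerebellum White Matter",
  "Cerebellar Vermal Lobules I-V",
  "Cerebellar Vermal Lobules VI-X"
 ],
 "cerebellar_gm": [
  "Left Cerebellum Exterior",
  "Right Cerebellum Exterior",
  "Cerebellar Vermal Lobules I-V",
  "Cerebellar Vermal Lobules VI-X"
 ],
 "centaur_meta_temporal": [
  "Left Entorhinal Area",
  "Right Entorhinal Area",
  "Left Amygdala",
  "Right Amygdala",
  "Left Parahippocampal Gyrus",
  "Right Parahippocampal Gyrus",
  "Left Fusiform Gyrus",
  "Right Fusiform Gyrus",
  "Left Inferior Temporal Gyrus",
  "Right Inferior Temporal Gyrus",
  "Left Middle Temporal Gyrus",
  "Right Middle Temporal Gyrus",
  "Left Temporal Pole",
  "Right Temporal Pole"
 ],
 "centiloid_cortex": [
  "Left Superior Frontal Gyrus",
  "Right Superior Frontal Gyrus",
  "Left Middle Frontal Gyrus",
  "Right Middle Frontal Gyrus",
  "Left Superior Frontal Gyrus Medial Segment",
  "Right Superior Frontal Gyrus Medial Segment",
  "Left Frontal Pole",
  "Right Frontal Pole",
  "Left Anterior Cingulate Gyrus",
  "Right Anterior Cingulate Gyrus",
  "Left Middle Cingulate Gyrus",
  "Right Middle Cingulate Gyrus",
  "Left Posterior Cingulate Gyrus",
  "Right Posterior Cingulate Gyrus",
  "Left Precuneus",
  "Right Precuneus",
  "Left Angular Gyrus",
  "Right Angular Gyrus",
  "Left Supramarginal Gyrus",
  "Right Supramarginal Gyrus",
  "Left Superior Parietal Lobule",
  "Right Superior Parietal Lobule",
  "Left Superior Temporal Gyrus",
  "Right Superior Temporal Gyrus",
  "Left Middle Temporal Gyrus",
  "Right Middle Temporal Gyrus",
  "Left Inferior Temporal Gyrus",
  "Right Inferior Temporal Gyrus"
 ]
}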