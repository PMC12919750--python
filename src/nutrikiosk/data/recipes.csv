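recipe_id,name,food_id,servings,meal_slots
tacos_frijol,Tacos de frijol,tortilla_maiz,2,breakfast;dinner
tacos_frijol,Tacos de frijol,frijol_negro_cocido,1,breakfast;dinner
ensalada_nopales,Ensalada de nopales,nopales_cocidos,1,lunch;dinner
ensalada_nopales,Ensalada de nopales,jitomate_crudo,0.5,lunch;dinner
ensalada_nopales,Ensalada de nopales,queso_fresco,0.5,lunch;dinner
mojarra_con_verduras,Mojarra con verduras,pescado_mojarra,2,lunch
mojarra_con_verduras,Mojarra con verduras,calabacita_cocida,1,lunch
mojarra_con_verduras,Mojarra con verduras,arroz_cocido,1,lunch
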